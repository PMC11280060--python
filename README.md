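# resinate

Analytics for drug–ion-exchange-resin complexation, built around solid-state
¹³C CPMAS NMR relaxometry and impedimetric electronic-tongue pattern
recognition — the workflow used to decide whether a bitter drug bound to a
taste-masking resin forms a true molecular complex or just a physical
mixture. The reference system is mefloquine hydrochloride (MQ, an
antimalarial with a strongly bitter quinoline core) bound to polacrilin
potassium (R, a weakly acidic methacrylate cation-exchange resin), giving
the resinate MQ–R.

The package is aimed at formulation scientists and NMR spectroscopists who
have variable-contact-time (VCT) CPMAS spectra, peak tables, e-tongue
impedance spectra or dissolution traces as plain text, and want tested,
scriptable versions of the standard analyses. A synthetic-data module stands
in for the spectrometer and the sensor array, so every stage is testable
end to end.

## The model

In a cross-polarization experiment the ¹³C signal of a carbon after a
Hartmann–Hahn contact of duration *t*c follows

    S(tc) = S0 · (1 − exp(−tc / TCH)) · exp(−tc / T1ρH)

a build-up governed by the local C–H dipolar coupling (time constant
*T*CH, μs) damped by proton rotating-frame relaxation (*T*1ρH, ms). The
curve peaks at the closed-form stationary point

    t* = TCH · ln(1 + T1ρH / TCH).

Because proton spin diffusion is fast in rigid solids, *T*1ρH is homogenized
over domains of a few nanometers: if the drug is intimately mixed with the
resin, its carbons inherit resin-like (short) *T*1ρH values; in a physical
mixture each component keeps its own. `resinate` fits the CP curve per
resolved carbon by bounded nonlinear least squares (analytic Jacobian,
asymptotic standard errors), then turns the spin-diffusion argument into an
explicit classifier with two configurable ratio thresholds.

The e-tongue stage fingerprints liquids by |Z|(f) over 1–10⁶ Hz across six
sensing units, projects the log-magnitude spectra to 2-D (Fastmap-initialized
force scheme, or classical MDS), and scores the class geometry with the
silhouette coefficient and class-centroid Euclidean distances; drug-release
traces are fitted with s(t) = baseline + amplitude·(1 − e^(−t/τ)), reporting
τ and t95 = τ·ln 20.

## Worked example

```python
import numpy as np
import resinate as rs

# --- CP dynamics: fit one carbon's VCT curve --------------------------
tc = np.geomspace(20, 50_000, 24)                       # contact times, us
rng = np.random.default_rng(1)
y = rs.eq1(tc, 100.0, 2420.0, 140.0)                    # C2 ground truth
y *= 1 + rng.normal(0, 0.02, tc.shape)                  # 2% noise
fit = rs.CPDynamicsModel.from_arrays(tc, y, assignment="C2",
                                     center=145.2).fit()
print(fit.summary())
```

```
CP dynamics fit [C2 @ 145.2 ppm]
==========================================================
status: ok   n=24   R^2=0.99984
----------------------------------------------------------
     param       estimate      std err
        S0          98.29        0.427
  TCH (us)           2361         22.5
 T1rH (ms)          158.7         4.24
   t* (us)         9967.9
==========================================================
```

The fitted build-up constant (2361 ± 23 μs vs the generating 2420 μs) and
rotating-frame relaxation (158.7 ± 4.2 ms vs 140 ms, within ~1.3 of the
quoted uncertainty at this noise level) place the curve maximum near
10,000 μs — the long-contact optimum characteristic of the pure drug.

```python
# --- e-tongue: project the three-class impedance set ------------------
iset = rs.generate_etongue_set(seed=7)          # MQ, MQ-R, R x 6 units x 3
X, labels = rs.feature_matrix(iset)
proj = rs.project_2d(X, labels, seed=7)
print(proj.summary())
```

```
2-D projection (force_scheme)
samples: 9   stress: 0.005945   silhouette: 0.9508
centroid distances:
         MQ   MQ-R      R
MQ    0.000  0.332  0.998
MQ-R  0.332  0.000  0.669
R     0.998  0.669  0.000
```

The three classes separate cleanly (silhouette 0.95); the resinate cluster
sits between drug and resin but nearer the drug
(d(MQ, MQ–R) = 0.33 < d(MQ–R, R) = 0.67), the signature of effective but
incomplete taste masking.

```python
# --- mixing verdict from relaxation tables ----------------------------
report = rs.classify_mixing(
    [("drug", v) for v in (22.2, 23.2, 19.1, 25.1, 21.6)]
    + [("resin", v) for v in (8.9, 10.5, 9.3)],
    pure_drug_fits=[114, 140, 153, 122, 123],
    pure_resin_fits=[9.7, 9.4, 9.0, 11.7])
print(report.verdict)        # -> complex
```

A command-line layer mirrors these steps (`resinate simulate vct`,
`resinate fit`, `resinate compare`, `resinate etongue`,
`resinate release`).

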