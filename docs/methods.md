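# Methods

## Scope and data model

`resinate` operates entirely in the frequency domain: its inputs are 1-D
¹³C CPMAS spectra (ppm, intensity), peak/assignment tables, e-tongue
impedance spectra (Hz, Ω) and dissolution traces (s, Ω), all as plain text.
No FID processing (apodization, FT, phasing) is performed, and only the
single-spin-pair CP model below is fitted — no oscillatory I–S transients,
Hartmann–Hahn mismatch, or bi-exponential rotating-frame decay.

Spectra store the ppm axis descending (NMR display convention); windows are
always `(lo, hi)` in ppm regardless of display order. The Larmor frequency,
when absent from metadata, is derived from the field strength with
γ(¹³C)/2π = 10.7084 MHz/T; the package default is the instrument-reported
100.61 MHz at 9.4 T.

## Cross-polarization dynamics

The per-carbon signal across a variable-contact-time (VCT) series is
modelled as

S(t_c) = S₀ · (1 − e^(−t_c/T_CH)) · e^(−t_c/T₁ρᴴ)

with a single internal microsecond time base; T₁ρᴴ is converted to ms only
at the reporting boundary. The stationary point is
t* = T_CH · ln(1 + T₁ρᴴ/T_CH); the curve is strictly increasing before it
and decreasing after.

Fitting is bounded nonlinear least squares (trust-region reflective) with
the analytic Jacobian, bounds T_CH ∈ [1, 10⁵] μs and T₁ρᴴ ∈ [0.1, 10⁴] ms,
and tight tolerances (ftol = xtol = gtol = 10⁻¹²) so that noiseless curves
are recovered to ~10⁻⁶ relative and the fit is scale-equivariant to 10⁻⁸.
Automatic initialization: S₀ ← 1.1·max(S); T_CH ← time of the first
half-maximum crossing on the rising limb (first crossing in time order when
noise creates several); T₁ρᴴ ← −1/slope of ln S regressed over the points
after the maximum. On non-convergence three deterministically perturbed
restarts are tried. Standard errors come from the asymptotic covariance
(s²·(JᵀJ)⁻¹ with s² = SSE/(n−3)) at the optimum.

A fit is reported `ok` only when converged with finite covariance and
relative se(T₁ρᴴ) < 100%; curves with fewer than 5 points, no positive
intensity, or an overlap-flagged peak are `n.d.` (mirroring the
"not determined" rows of relaxation tables); T₁ρᴴ running into its upper
bound is `poor_fit`. Two readout modes exist, trapezoidal window area
(default) and window height — for constant-width lineshapes they are
proportional, and both pass the recovery tests.

Conditioning: with 24 log-spaced contact times in [20, 50 000] μs and 2%
multiplicative noise, se(T₁ρᴴ) stays at the few-percent level down to
T₁ρᴴ(μs)/T_CH ≈ 1; only when the decay is faster than the build-up
(ratio ≲ 1) does the uncertainty inflate substantially (measured ~15%
relative se at ratio 0.2). The fit reports that inflation honestly rather
than a silently precise value.

## Mixing-state inference

Chemical-shift comparison pairs same-assignment peaks between a reference
table (solid pure drug by default; the DMSO solution shifts are provided as
an alternative reference frame) and the complex. Multi-component (unfolded)
signals are paired order-preservingly — the k-th highest-frequency
component against the k-th — which is the standard no-crossing convention
for tracking shift perturbations; when multiplicities differ each reference
entry takes the nearest unused partner. Positive Δδ = deshielded; |Δδ|
within the threshold (default 1.0 ppm, the interval used in shift-variation
bar plots) is `unchanged`; increased multiplicity is `split`; signals
buried under the other component are `overlap`.

The spin-diffusion verdict aggregates per-carbon T₁ρᴴ by median (robust to
single outlying carbons, e.g. one anomalously slow-relaxing CH). With
reduction factor r = 2 and convergence factor c = 5:

* `complex` — median drug T₁ρᴴ in the sample ≤ (pure-drug median)/r AND
  (drug median)/(resin median in the sample) ≤ c;
* `physical_mixture` — both components' sample medians within a factor r of
  their pure-phase medians;
* `indeterminate` — anything else, or fewer than two usable drug fits.

The published criterion is qualitative ("similar T₁ρᴴ because spin
diffusion is fast"); r and c are this package's explicit operating points,
chosen so that a 5–10× drug relaxation drop with near-resin values
classifies as complex with margin while unchanged components classify as a
mixture, and both are exposed as parameters. The rule is monotone: lowering
every sample drug T₁ρᴴ can never flip a complex verdict to
physical_mixture.

## Synthetic-data generators

The generators define the study conditions the tests run under.

**VCT series.** Default sample specifications carry the published
per-carbon ground truth for the pure drug, the pure resin, the resinate and
their 1:1 physical mixture; the mixture spec is the plain union of the two
pure-component site lists with unchanged time constants, so complex and
mixture fixtures differ *only* in the drug sites' T₁ρᴴ (plus complexation
shift edits) — a controlled contrast for the classifier. Sites whose
parameters were not determined experimentally carry shifts only. Lines are
peak-normalized Lorentzians (Gaussian optional) with amplitude
S(t_c)/n_shifts per component of an unfolded signal (equal S₀ sharing, and
equal total S₀ per component of the 1:1 w/w complex — molar responses are
not modelled). Default linewidths: 60 Hz for crystalline drug sites, 300 Hz
for the amorphous resin — narrow enough to resolve the 1.6-ppm aliphatic
C–OH triplet at 100.61 MHz, broad enough to reproduce the resin envelope.
Contact grid: 24 log-spaced points over the acquisition range
[20, 50 000] μs. Noise, drawn once per (contact time, axis point):
I·(1 + N(0, σ_mult)) + N(0, σ_add·max S₀) with defaults σ_mult = 2%,
σ_add = 0.1% — the multiplicative level at which the recovery tests are
specified, plus a small detection floor. First-order spinning sidebands at
±ν_r/ν_L (97.4 ppm at 9800 Hz) can be synthesized at 10% isotropic
amplitude (off by default). Fixed seed ⇒ bit-identical output. The
generator calls the same amplitude law the fitter optimizes, and a test
verifies generator→fitter round trips to machine precision.

**E-tongue sets.** Each class × sensing-unit response is a 4-parameter
log-logistic step in log-frequency between a low- and a high-frequency
plateau — no equivalent-circuit claim, just a smooth strictly positive,
strictly decreasing |Z|(f) family with controllable class separation. The
three default classes place the resinate between drug and resin on the
response axis at 35% of the way from the drug, encoding the incomplete
taste-masking geometry d(MQ, MQ–R) < d(MQ–R, R) < d(MQ, R) that projection
and clustering must preserve. Six units, three replicates, multiplicative
log-normal replicate jitter (CV 3% default, positivity guaranteed).

**Dissolution.** |Z|(t) = Z_end + (Z_start − Z_end)·e^(−t/τ) with a paired
constant blank under the same multiplicative noise; defaults τ = 68.1 s and
753 → 827 Ω over 5 min, the reported release conditions.

What the generators do **not** emulate: baseline roll and phase errors,
t₁ noise or spinning instabilities in the spectra; sensor drift, electrode
aging or temperature effects in the impedance data; multi-stage or
Fickian-diffusion release. Passing tests therefore demonstrate correctness
of the estimators under the assumed noise structure, not robustness to
every instrumental artifact.

## E-tongue analytics

Features are the concatenated per-unit log₁₀|Z| vectors (unit-major,
frequency-minor), one row per (class, replicate). Log-magnitudes are
already commensurate across units and frequencies, so the default applies
no further scaling — with few samples and hundreds of features, per-feature
unit-variance standardization mostly amplifies directions that carry only
replicate noise (it lowers the default fixture's class separation
markedly); it remains available for arrays whose units differ wildly in
dynamic range.

Two projections satisfy the same contract: a documented force scheme —
Fastmap-style initialization from farthest-pair pivots, then 50 sweeps in
which every point moves along its line to each other point by a fraction of
(normalized data distance − current 2-D distance), the fraction annealing
geometrically 0.3 → 0.01 — and classical metric MDS (double-centered
eigendecomposition, deterministic sign convention). Stress is the
Kruskal-style normalized residual with the optimal uniform scale applied,
so exactly embeddable configurations score 0. The force scheme tracks
stress per sweep and returns the best configuration seen, so the reported
stress never exceeds the initial one. Silhouette uses the standard
(b − a)/max(a, b) definition, singleton classes contributing 0, computed on
the projected coordinates by default (matching figure-level claims) with a
data-space option; a brute-force double loop and scikit-learn serve as
independent oracles in the tests. Hierarchical clustering is agglomerative
with Euclidean distances (average linkage by default; complete and single
available), reported with the class-centroid distance table. Degenerate
all-identical inputs yield a flagged zero-stress result with undefined
silhouette rather than an error.

## Release kinetics

The derived signal (default: pointwise difference |Z| − |Z₀| against the
blank; ratio mode available) is fitted with
s(t) = baseline + amplitude·(1 − e^(−t/τ)) by bounded least squares with
analytic Jacobian. The reported release time is t95 = τ·ln 20 — the time to
95% of the asymptotic change — stated explicitly because "released within X
minutes" is otherwise ambiguous (τ, 3τ and plateau criteria all circulate).
Precision depends strongly on the amplitude-to-baseline ratio: multiplicative
noise acts on the full impedance, so with the default trace (74 Ω change on
a ~790 Ω baseline) a 3% CV propagates to ~45% per-point noise on the
difference signal and τ is only determined to roughly ±30% per run, whereas
amplitude-dominated traces recover τ to a few percent at the same CV. The
recovery property test uses an amplitude-dominated trace for that reason;
constant signals are flagged as failed fits, not exceptions.

## Numerical conventions and edge cases

* Peak picking: prominence threshold as a fraction of the maximum, greedy
  taller-first suppression within the minimum separation, windows at the
  nearest flanking local minima; flat spectra give an empty table.
* Integration: trapezoidal over the window; windows clipped to grid points
  tile additively. The ±5-linewidth synthesis truncation keeps ~94% of a
  Lorentzian's area — a constant factor that cancels in dynamics fitting.
* Sideband flagging compares only against *stronger* peaks (peak height as
  recorded by the picker), is idempotent, and never flags the strongest
  member of a family; the match tolerance is 1 ppm by default.
* Assignment joining: nearest center within a 0.5 ppm gate; unmatched peaks
  keep empty assignments.
* Referencing is an exact axis translation; the applied offset accumulates
  in metadata.
* JCAMP-DX support is read-only, single-block `##XYDATA=(X++(Y..Y))` with
  AFFN values — enough for interchange, deliberately not a full
  implementation of the standard.

## Known limitations

* The CP model is the single-exponential build-up/decay product; systems
  with oscillatory transients or multi-component rotating-frame decay need
  models outside this package's scope.
* Overlap handling is binary (a peak is usable or `n.d.`); no deconvolution
  of overlapped signals is attempted.
* The mixing thresholds are operating points, not fitted quantities; highly
  heterogeneous samples may legitimately fall into `indeterminate`.
* The force-scheme projection is seeded and deterministic but, like all
  iterative layouts, only locally optimal; classical MDS is provided as the
  closed-form alternative.
* Problem sizes throughout (24-point contact grids, 4096-point axes,
  9-sample e-tongue sets, ≤50-replicate simulations) are chosen to exercise
  every estimator at the fidelity the analyses need while keeping the whole
  suite interactive-fast.
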