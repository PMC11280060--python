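"""Synthetic data with the statistical structure the analysis assumes.

Three generators stand in for the instruments:

* variable-contact-time (VCT) spectral series — per-carbon CP build-up/decay
  amplitudes rendered as Lorentzian (optionally Gaussian) lines on a shared
  ppm axis, with multiplicative + additive Gaussian noise;
* impedimetric electronic-tongue sets — three liquid classes (pure drug MQ,
  pure resin R, resinate MQ-R) measured over 1-10^6 Hz by six sensing units;
* dissolution traces — single-exponential impedance change with a paired
  constant blank.

The default sample specifications are seeded from the published relaxation
tables for mefloquine hydrochloride (MQ), polacrilin potassium (R), their
resinate complex (MQ-R) and the physical mixture (MQ+R): per-carbon chemical
shifts, TCH (us) and T1rhoH (ms). Sites whose relaxation parameters were not
determined carry shifts only and are excluded from dynamics fixtures. The
physical-mixture spec is, by construction, the plain union of the MQ and R
sites with each component's own time constants unchanged — so MQ-R and MQ+R
differ only in the drug sites' T1rhoH values (and the complexation shift
edits), which is exactly the contrast the mixing classifier must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import config
from .errors import ContractError
from .specmodel import Peak, PeakTable, Spectrum
from .etongue import DissolutionCurve, ImpedanceSet, ImpedanceSpectrum

__all__ = [
    "CarbonSite",
    "SampleSpec",
    "ImpedanceClassParams",
    "default_sample_specs",
    "default_peak_table",
    "default_etongue_params",
    "generate_vct_series",
    "generate_etongue_set",
    "generate_dissolution",
    "MQ_SOLUTION_SHIFTS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CarbonSite:
    """Ground truth for one carbon signal (possibly unfolded over several
    shifts). ``TCH``/``T1rhoH`` of None marks a not-determined site: it keeps
    its shift(s) for shift-table fixtures but contributes no dynamics."""

    assignment: str
    shifts: tuple[float, ...]        # ppm; >1 entry models unfolding
    TCH: float | None = None         # us
    T1rhoH: float | None = None      # ms
    S0: float = 100.0                # total equilibrium amplitude
    linewidth: float = config.DRUG_LINEWIDTH_HZ  # Hz FWHM
    component: str = "drug"          # {"drug", "resin"}
    overlap_group: str | None = None

    def __post_init__(self):
        if isinstance(self.shifts, (int, float)):
            self.shifts = (float(self.shifts),)
        else:
            self.shifts = tuple(float(s) for s in self.shifts)
        if self.S0 <= 0 or self.linewidth <= 0:
            raise ContractError("S0 and linewidth must be > 0")
        if self.TCH is not None and self.TCH <= 0:
            raise ContractError("TCH must be > 0 when present")
        if self.T1rhoH is not None and self.T1rhoH <= 0:
            raise ContractError("T1rhoH must be > 0 when present")

    @property
    def has_dynamics(self) -> bool:
        return self.TCH is not None and self.T1rhoH is not None


@dataclass
class SampleSpec:
    """A simulated sample: a set of carbon sites plus noise levels.

    ``noise_mult`` is the fractional sd of per-point multiplicative noise;
    ``noise_add`` the sd of additive noise as a fraction of the largest site
    amplitude.
    """

    sample_id: str
    sites: list[CarbonSite]
    noise_mult: float = 0.02
    noise_add: float = 0.001

    def __post_init__(self):
        if not self.sites:
            raise ContractError("sites must be non-empty")
        if self.noise_mult < 0 or self.noise_add < 0:
            raise ContractError("noise parameters must be >= 0")

    def site(self, assignment: str) -> CarbonSite:
        """First site with the given assignment (duplicates permitted)."""
        for s in self.sites:
            if s.assignment == assignment:
                return s
        raise KeyError(assignment)

    def dynamics_sites(self) -> list[CarbonSite]:
        return [s for s in self.sites
                if s.has_dynamics and s.overlap_group is None]

    @property
    def max_S0(self) -> float:
        return max(s.S0 for s in self.sites)


@dataclass
class ImpedanceClassParams:
    """Per-class e-tongue ground truth: one smooth monotone |Z|(f) curve per
    sensing unit, parameterized as a log-logistic step in log-frequency
    between a low-frequency and a high-frequency plateau."""

    class_label: str
    z_low: tuple[float, ...]        # low-frequency plateau, ohm, per unit
    z_high: tuple[float, ...]       # high-frequency plateau, ohm, per unit
    f_transition: tuple[float, ...]  # Hz, per unit
    slope: tuple[float, ...]        # log-logistic steepness, per unit
    replicate_cv: float = 0.03

    def __post_init__(self):
        n = len(self.z_low)
        if not (len(self.z_high) == len(self.f_transition)
                == len(self.slope) == n):
            raise ContractError("per-unit parameter tuples must align")
        if any(z <= 0 for z in self.z_low + self.z_high):
            raise ContractError("plateaus must be > 0")
        if any(not (1.0 <= f <= 1e6) for f in self.f_transition):
            raise ContractError("transition frequency must lie in 1-10^6 Hz")
        if self.replicate_cv < 0:
            raise ContractError("replicate_cv must be >= 0")

    @property
    def n_units(self) -> int:
        return len(self.z_low)

    def mean_curve(self, freqs: np.ndarray, unit: int) -> np.ndarray:
        """Noise-free |Z|(f) for one sensing unit."""
        llo = np.log10(self.z_low[unit])
        lhi = np.log10(self.z_high[unit])
        f0, k = self.f_transition[unit], self.slope[unit]
        return 10.0 ** (lhi + (llo - lhi) / (1.0 + (freqs / f0) ** k))


# ---------------------------------------------------------------------------
# published-table ground truth
# ---------------------------------------------------------------------------

# (assignment, shifts, TCH us, T1rhoH ms) — pure mefloquine hydrochloride.
_MQ_ROWS = [
    ("C4", (148.5,), 978.0, 114.0),
    ("C4", (148.1,), 1000.0, 110.0),
    ("C2", (145.2,), 2420.0, 140.0),
    ("C8a", (143.8,), 6380.0, 153.0),
    ("C7", (130.1,), 1950.0, 212.0),
    ("C5", (127.1,), 689.0, 122.0),
    ("C5", (126.5,), 725.0, 119.0),
    ("C6", (125.6,), 1620.0, 142.0),
    ("C6", (125.2,), None, None),
    ("C8", (123.1,), None, None),
    ("8-CF3", (122.7,), None, None),
    ("C4a", (121.9,), None, None),
    ("2-CF3", (119.0,), None, None),
    ("C3", (114.4,), 737.0, 123.0),
    ("C11", (67.8,), 440.0, 115.0),
    ("C12", (59.5,), 310.0, 117.0),
    ("C12", (59.0,), 406.0, 111.0),
    ("C14", (47.7,), 457.0, 123.0),
    ("C14", (47.3,), 461.0, 121.0),
    ("C15", (22.3,), 302.0, 124.0),
    ("C17", (21.5,), 433.0, 117.0),
    ("C16", (21.0,), 438.0, 118.0),
]

# Drug sites inside the resinate complex. Overlap-with-resin rows keep their
# pure-MQ shift but are flagged and carry no dynamics (reported n.d.).
_MQR_DRUG_ROWS = [
    ("C4", (154.9,), None, None, None),
    ("C4", (151.6,), 705.0, 57.3, None),
    ("C2", (148.0,), 1150.0, 22.2, None),
    ("C2", (147.3,), 1220.0, 23.2, None),
    ("C8a", (144.1,), 2410.0, 49.1, None),
    ("C8a", (143.6,), 2620.0, 35.6, None),
    ("C7", (128.8,), 695.0, 19.1, None),
    ("C5", (128.0,), 675.0, 25.1, None),
    ("C5", (127.5,), 614.0, 21.6, None),
    ("C6", (126.6,), 746.0, 32.3, None),
    ("C6", (126.0,), 564.0, 27.9, None),
    ("C8", (122.9,), None, None, None),
    ("8-CF3", (122.9,), None, None, None),
    ("C4a", (122.9,), None, None, None),
    ("2-CF3", (120.0,), None, None, None),
    ("C3", (115.3,), 532.0, 22.5, None),
    ("C3", (114.7,), None, None, None),
    ("C11", (70.2, 68.6, 66.9), 67.8, 68.4, None),
    ("C12", (58.1,), 68.1, 14.8, None),
    ("C14", (47.7,), None, None, "R"),
    ("C15", (22.3,), None, None, "R"),
    ("C17", (21.5,), None, None, "R"),
    ("C16", (21.0,), None, None, "R"),
]

# Pure polacrilin potassium resin.
_R_ROWS = [
    ("C1 (CO2-K+)", (186.5, 185.6), 1930.0, 9.7),
    ("C1'arom.", (148.4,), None, None),
    ("C2'arom.", (129.6, 127.8), None, None),
    ("C2, C3, C4, C5", (57.0,), 99.0, 9.4),
    ("C2, C3, C4, C5", (47.0,), 640.0, 9.0),
    ("C6", (20.0,), 355.0, 11.7),
]

# Resin sites inside the resinate complex.
_MQR_RESIN_ROWS = [
    ("C1 (CO2-K+)", (187.3,), 1190.0, 8.9, None),
    ("C1'arom.", (148.4,), None, None, "MQ"),
    ("C2'arom.", (129.6, 127.8), None, None, "MQ"),
    ("C2, C3, C4, C5", (57.0,), 68.0, 14.8, None),
    ("C2, C3, C4, C5", (46.0,), 281.0, 10.5, None),
    ("C6", (18.0,), 280.0, 9.3, None),
]

#: Solution-state (DMSO) mefloquine shifts, for the solution-reference mode
#: of the chemical-shift comparison.
MQ_SOLUTION_SHIFTS = {
    "C4": 151.71, "C2": 147.13, "C8a": 143.22, "C7": 130.39, "C5": 129.72,
    "C6": 128.83, "C8": 127.57, "8-CF3": 124.12, "C4a": 126.85,
    "2-CF3": 121.65, "C3": 115.84, "C11": 68.01, "C12": 59.19, "C14": 44.69,
    "C15": 22.02, "C16": 21.27, "C17": 21.56,
}


def _drug_sites(rows):
    return [CarbonSite(a, s, tch, t1r,
                       linewidth=config.DRUG_LINEWIDTH_HZ, component="drug")
            for a, s, tch, t1r in rows]


def default_sample_specs() -> dict[str, SampleSpec]:
    """Sample specifications for the four study samples.

    Keys: ``MQ`` (pure drug), ``R`` (pure resin), ``MQ-R`` (resinate
    complex), ``MQ+R`` (1:1 physical mixture = plain union of MQ and R sites
    with unchanged time constants).
    """
    mq_sites = _drug_sites(_MQ_ROWS)
    r_sites = [CarbonSite(a, s, tch, t1r,
                          linewidth=config.RESIN_LINEWIDTH_HZ,
                          component="resin")
               for a, s, tch, t1r in _R_ROWS]
    mqr_sites = (
        [CarbonSite(a, s, tch, t1r, linewidth=config.DRUG_LINEWIDTH_HZ,
                    component="drug", overlap_group=og)
         for a, s, tch, t1r, og in _MQR_DRUG_ROWS]
        + [CarbonSite(a, s, tch, t1r, linewidth=config.RESIN_LINEWIDTH_HZ,
                      component="resin", overlap_group=og)
           for a, s, tch, t1r, og in _MQR_RESIN_ROWS]
    )
    mix_sites = [replace(s) for s in mq_sites] + [replace(s) for s in r_sites]
    return {
        "MQ": SampleSpec("MQ", mq_sites),
        "R": SampleSpec("R", r_sites),
        "MQ-R": SampleSpec("MQ-R", mqr_sites),
        "MQ+R": SampleSpec("MQ+R", mix_sites),
    }


def default_peak_table(spec: SampleSpec,
                       half_width_ppm: float = 2.0) -> PeakTable:
    """Integration peak table for a sample spec.

    One peak per (site, shift), windows capped at ``half_width_ppm`` and
    clipped at midpoints between neighbouring entries so they stay disjoint.
    Overlap-flagged sites keep their flag (their fits report n.d.).
    """
    entries = []
    for site in spec.sites:
        for shift in site.shifts:
            entries.append((shift, site))
    entries.sort(key=lambda e: -e[0])
    centers = np.array([e[0] for e in entries])
    peaks = []
    for i, (c, site) in enumerate(entries):
        hi = c + half_width_ppm
        lo = c - half_width_ppm
        if i > 0:
            hi = min(hi, 0.5 * (centers[i - 1] + c))
        if i < len(entries) - 1:
            lo = max(lo, 0.5 * (c + centers[i + 1]))
        if hi <= lo:  # coincident shifts (distinct n.d. sites): skip window
            continue
        peaks.append(Peak(c, site.assignment, (lo, hi),
                          overlap_group=site.overlap_group,
                          component=site.component))
    table = PeakTable.__new__(PeakTable)
    table.peaks = peaks
    table.sample_id = spec.sample_id
    return table


# ---------------------------------------------------------------------------
# VCT series generator
# ---------------------------------------------------------------------------

def _lineshape(axis: np.ndarray, center: float, fwhm_ppm: float,
               kind: str) -> np.ndarray:
    """Peak-normalized lineshape (height 1 at center)."""
    if kind == "lorentzian":
        hw = 0.5 * fwhm_ppm
        return hw**2 / ((axis - center) ** 2 + hw**2)
    if kind == "gaussian":
        sigma = fwhm_ppm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((axis - center) / sigma) ** 2)
    raise ContractError(f"unknown lineshape {kind!r}")


def generate_vct_series(
    spec: SampleSpec,
    contact_times=None,
    axis: tuple[float, float, int] = (-5.0, 210.0, 4096),
    seed: int = 0,
    lineshape: str = "lorentzian",
    larmor_mhz: float = config.DEFAULT_LARMOR_MHZ,
    sidebands: bool = False,
) -> list[Spectrum]:
    """Simulate one CPMAS spectrum per contact time (a VCT series).

    Each dynamics-carrying site contributes, at each of its shifts, a
    peak-normalized line with amplitude ``S(tc)/len(shifts)`` following the
    CP build-up/decay law; linewidths convert from Hz to ppm at
    ``larmor_mhz``. Noise is drawn once per (contact time, axis point):
    ``I*(1 + N(0, noise_mult)) + N(0, noise_add * max S0)``. Fixed seed gives
    bit-identical output. With ``sidebands=True``, first-order spinning
    sidebands at +/- spin_rate/larmor ppm are added at 10% of the isotropic
    amplitude.

    If the axis is too coarse to separate the narrowest declared splitting,
    a warning string is recorded in each spectrum's metadata (the series is
    still produced).
    """
    from .cpdyn import eq1  # single shared amplitude law with the fitter

    if contact_times is None:
        lo, hi = config.CONTACT_TIME_RANGE_US
        contact_times = np.geomspace(lo, hi, config.DEFAULT_N_CONTACT_TIMES)
    tc = np.asarray(contact_times, dtype=float)
    if np.any(tc <= 0) or (len(tc) > 1 and not np.all(np.diff(tc) > 0)):
        raise ContractError("contact_times must be strictly increasing, > 0")
    lo, hi, n = axis
    if n < 512:
        raise ContractError("axis must have at least 512 points")
    ppm = np.linspace(lo, hi, int(n))
    step = ppm[1] - ppm[0]

    warning = None
    gaps = []
    by_assignment: dict[str, list[float]] = {}
    for site in spec.sites:
        by_assignment.setdefault(site.assignment, []).extend(site.shifts)
    for shifts in by_assignment.values():
        ss = sorted(shifts)
        gaps += [b - a for a, b in zip(ss, ss[1:]) if b > a]
    if gaps and step > min(gaps):
        warning = (f"axis step {step:.3f} ppm coarser than narrowest "
                   f"declared splitting {min(gaps):.3f} ppm")

    rng = np.random.default_rng(seed)
    sideband_ppm = config.DEFAULT_SPIN_RATE_HZ / larmor_mhz
    series = []
    for t in tc:
        clean = np.zeros_like(ppm)
        for site in spec.dynamics_sites():
            amp = eq1(t, site.S0, site.TCH, site.T1rhoH) / len(site.shifts)
            fwhm_ppm = site.linewidth / larmor_mhz
            for shift in site.shifts:
                clean += amp * _lineshape(ppm, shift, fwhm_ppm, lineshape)
                if sidebands:
                    for sgn in (+1, -1):
                        clean += 0.1 * amp * _lineshape(
                            ppm, shift + sgn * sideband_ppm, fwhm_ppm,
                            lineshape)
        noisy = (clean * (1.0 + rng.normal(0.0, spec.noise_mult, clean.shape))
                 + rng.normal(0.0, spec.noise_add * spec.max_S0, clean.shape))
        meta = {
            "sample_id": spec.sample_id,
            "contact_time": float(t),
            "spin_rate": config.DEFAULT_SPIN_RATE_HZ,
            "field_strength": config.DEFAULT_FIELD_T,
            "larmor_freq": larmor_mhz,
            "recycle_delay": config.DEFAULT_RECYCLE_DELAY_S,
            "nucleus": "13C",
        }
        if warning:
            meta["warning"] = warning
        # axis built ascending; Spectrum flips to display order
        series.append(Spectrum(ppm.copy(), noisy, meta))
    return series


# ---------------------------------------------------------------------------
# e-tongue generators
# ---------------------------------------------------------------------------

def default_etongue_params(
    n_units: int = 6,
    replicate_cv: float = 0.03,
) -> list[ImpedanceClassParams]:
    """Three-class ground truth: MQ and R at opposite edges of the response
    space, the resinate MQ-R between them and nearer MQ (the incomplete
    taste-masking geometry: mean-curve distances obey
    d(MQ, MQ-R) < d(MQ-R, R) < d(MQ, R))."""
    # class position along the drug->resin response axis
    positions = {"MQ": 0.0, "MQ-R": 0.35, "R": 1.0}
    out = []
    for label, x in positions.items():
        z_low, z_high, f0, slope = [], [], [], []
        for u in range(n_units):
            z_low.append(10 ** (5.0 + 0.12 * u + 0.9 * x))
            z_high.append(10 ** (2.3 + 0.08 * u - 0.35 * x))
            f0.append(10 ** (2.2 + 0.25 * u + 0.45 * x))
            slope.append(0.9 + 0.08 * u)
        out.append(ImpedanceClassParams(label, tuple(z_low), tuple(z_high),
                                        tuple(f0), tuple(slope),
                                        replicate_cv=replicate_cv))
    return out


def generate_etongue_set(
    params: list[ImpedanceClassParams] | None = None,
    n_freq: int = 50,
    n_replicates: int = 3,
    seed: int = 0,
    f_range: tuple[float, float] = (1.0, 1e6),
) -> ImpedanceSet:
    """Simulate labelled impedance spectra for every (class, unit, replicate).

    Frequencies are log-spaced over ``f_range`` (1-10^6 Hz by default);
    replicate jitter is multiplicative log-normal with the class's
    ``replicate_cv``, keeping |Z| strictly positive for every seed.
    """
    if params is None:
        params = default_etongue_params()
    if len(params) < 2:
        raise ContractError("need >= 2 classes")
    if n_freq < 10:
        raise ContractError("n_freq must be >= 10")
    if n_replicates < 2:
        raise ContractError("n_replicates must be >= 2")
    flo, fhi = f_range
    if not (flo > 0 and fhi > flo):
        raise ContractError("invalid frequency bounds")
    freqs = np.geomspace(flo, fhi, n_freq)
    rng = np.random.default_rng(seed)
    spectra = []
    n_units = params[0].n_units
    units = [f"SU{u + 1}" for u in range(n_units)]
    for cls in params:
        if cls.n_units != n_units:
            raise ContractError("all classes must share the unit count")
        for rep in range(1, n_replicates + 1):
            for u in range(n_units):
                mean = cls.mean_curve(freqs, u)
                jitter = (np.exp(rng.normal(0.0, cls.replicate_cv,
                                            mean.shape))
                          if cls.replicate_cv > 0 else 1.0)
                spectra.append(ImpedanceSpectrum(
                    frequencies=freqs.copy(),
                    magnitude=mean * jitter,
                    class_label=cls.class_label,
                    sensing_unit=units[u],
                    replicate=rep,
                ))
    return ImpedanceSet(spectra=spectra, units=units)


def generate_dissolution(
    tau: float = 68.1,
    Z_start: float = 753.0,
    Z_end: float = 827.0,
    duration: float = 300.0,
    dt: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DissolutionCurve:
    """Simulate a drug-release trace monitored by impedance at fixed
    frequency: ``|Z|(t) = Z_end + (Z_start - Z_end) * exp(-t / tau)`` with a
    paired constant blank ``|Z0|(t) = Z_start`` under the same multiplicative
    noise model. Default time constant and impedance span follow the
    release-kinetics study conditions (tau 68.1 s, ~753 -> 827 ohm over
    5 min)."""
    if tau <= 0:
        raise ContractError("tau must be > 0")
    if dt <= 0 or duration <= 0:
        raise ContractError("dt and duration must be > 0")
    warning = None
    if duration < 3.0 * tau:
        warning = f"duration {duration} s < 3*tau; tail poorly constrained"
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    z = Z_end + (Z_start - Z_end) * np.exp(-t / tau)
    z0 = np.full_like(t, Z_start)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        z = z * np.exp(rng.normal(0.0, noise_cv, t.shape))
        z0 = z0 * np.exp(rng.normal(0.0, noise_cv, t.shape))
    return DissolutionCurve(time=t, Z_sample=z, Z_blank=z0, warning=warning)
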