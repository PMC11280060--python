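"""Cross-polarization dynamics: the variable-contact-time (VCT) model.

In a CPMAS experiment the carbon signal observed after a Hartmann-Hahn
contact of duration ``tc`` follows

    S(tc) = S0 * (1 - exp(-tc / TCH)) * exp(-tc / T1rhoH)

a build-up with time constant ``TCH`` (set by the local C-H dipolar coupling)
damped by the proton rotating-frame relaxation ``T1rhoH`` (homogenized across
a phase by proton spin diffusion, hence a probe of nanometer-scale mixing).
Fitting this curve per resolved carbon gives the (S0, TCH, T1rhoH) triples
that the mixing analysis consumes.

The fit is exposed statsmodels-style: build a :class:`CPDynamicsModel` from a
:class:`VCTCurve` (or raw arrays), call :meth:`~CPDynamicsModel.fit`, and get
a :class:`CPDynamicsResults` carrying estimates, standard errors, covariance,
diagnostics and a ``summary()`` table. ``fit_cp_dynamics`` is the one-call
functional wrapper.

All internal arithmetic uses a single microsecond time base; ``T1rhoH`` is
reported in ms (the convention of relaxation tables) via explicit unit
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from . import config, specmodel
from .errors import ContractError

__all__ = [
    "eq1",
    "t_max",
    "VCTCurve",
    "CPDynamicsModel",
    "CPDynamicsResults",
    "CPFit",
    "extract_vct_curve",
    "fit_cp_dynamics",
    "fit_sample_table",
]

_MS_TO_US = 1000.0


def eq1(tc, S0: float, TCH: float, T1rhoH: float):
    """CP build-up/decay amplitude at contact time ``tc``.

    Parameters
    ----------
    tc : float or array
        Contact time in us, >= 0.
    S0 : float
        Equilibrium CP amplitude (arbitrary units).
    TCH : float
        Cross-polarization build-up time constant, us, > 0.
    T1rhoH : float
        Proton rotating-frame relaxation time, ms, > 0 (converted to us
        internally so both exponentials share one time base).
    """
    if TCH <= 0 or T1rhoH <= 0:
        raise ContractError("TCH and T1rhoH must be > 0")
    tc = np.asarray(tc, dtype=float)
    if np.any(tc < 0):
        raise ContractError("contact time must be >= 0")
    t1r_us = T1rhoH * _MS_TO_US
    out = S0 * (1.0 - np.exp(-tc / TCH)) * np.exp(-tc / t1r_us)
    return out if out.ndim else float(out)


def t_max(TCH: float, T1rhoH: float) -> float:
    """Contact time (us) at which the CP curve attains its maximum.

    Setting dS/dtc = 0 in the build-up/decay product gives the closed form
    ``t* = TCH * ln(1 + T1rhoH/TCH)`` (T1rhoH converted from ms to us).
    The curve is increasing before and decreasing after this point.
    """
    if TCH <= 0 or T1rhoH <= 0:
        raise ContractError("TCH and T1rhoH must be > 0")
    t1r_us = T1rhoH * _MS_TO_US
    return float(TCH * np.log1p(t1r_us / TCH))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class VCTCurve:
    """Signal readout of one peak across a contact-time series."""

    assignment: str
    center: float
    contact_times: np.ndarray  # us, strictly increasing
    intensities: np.ndarray
    readout_mode: str = "area"
    contaminated: bool = False  # overlap-flagged peak: fit reports n.d.

    def __post_init__(self):
        tc = np.asarray(self.contact_times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if len(tc) != len(y):
            raise ContractError("contact_times and intensities lengths differ")
        if len(tc) >= 2 and not np.all(np.diff(tc) > 0):
            raise ContractError("contact_times must be strictly increasing")
        self.contact_times = tc
        self.intensities = y

    def __len__(self) -> int:
        return len(self.contact_times)


@dataclass
class CPDynamicsResults:
    """Fitted CP-dynamics parameters with uncertainties and diagnostics.

    One such object corresponds to one row of a relaxation table:
    (delta, TCH +/- se, T1rhoH +/- se) for a single carbon signal.
    ``status`` is ``"ok"`` for a converged, well-conditioned fit, ``"n.d."``
    when the fit was not attempted or did not converge (mirroring the
    "not determined" entries of overlap-contaminated signals), and
    ``"poor_fit"`` when T1rhoH ran into its upper bound.
    """

    S0: float = np.nan
    S0_se: float = np.nan
    TCH_us: float = np.nan
    TCH_se: float = np.nan
    T1rhoH_ms: float = np.nan
    T1rhoH_se: float = np.nan
    covariance: np.ndarray | None = None  # 3x3, (S0, TCH_us, T1rhoH_ms)
    r_squared: float = np.nan
    n_points: int = 0
    converged: bool = False
    status: str = "n.d."
    message: str = ""
    assignment: str = ""
    center: float = np.nan

    def __post_init__(self):
        if self.status == "ok":
            assert self.TCH_us > 0 and self.T1rhoH_ms > 0

    @property
    def params(self) -> np.ndarray:
        """(S0, TCH_us, T1rhoH_ms)."""
        return np.array([self.S0, self.TCH_us, self.T1rhoH_ms])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.S0_se, self.TCH_se, self.T1rhoH_se])

    @property
    def t_max_us(self) -> float:
        """Contact time of the fitted curve's maximum, us."""
        return t_max(self.TCH_us, self.T1rhoH_ms)

    def predict(self, tc) -> np.ndarray:
        return eq1(tc, self.S0, self.TCH_us, self.T1rhoH_ms)

    def summary(self) -> str:
        head = f"CP dynamics fit"
        if self.assignment:
            head += f" [{self.assignment} @ {self.center:.1f} ppm]"
        lines = [
            head,
            "=" * 58,
            f"status: {self.status}   n={self.n_points}   "
            f"R^2={self.r_squared:.5f}" if np.isfinite(self.r_squared)
            else f"status: {self.status}   n={self.n_points}",
            "-" * 58,
            f"{'param':>10} {'estimate':>14} {'std err':>12}",
            f"{'S0':>10} {self.S0:>14.4g} {self.S0_se:>12.3g}",
            f"{'TCH (us)':>10} {self.TCH_us:>14.4g} {self.TCH_se:>12.3g}",
            f"{'T1rH (ms)':>10} {self.T1rhoH_ms:>14.4g} {self.T1rhoH_se:>12.3g}",
        ]
        if self.status == "ok":
            lines.append(f"{'t* (us)':>10} {self.t_max_us:>14.5g}")
        lines.append("=" * 58)
        return "\n".join(lines)


#: Table-row alias: one fitted (S0, TCH, T1rhoH) record.
CPFit = CPDynamicsResults


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _nd(curve: VCTCurve | None, msg: str) -> CPDynamicsResults:
    return CPDynamicsResults(
        status="n.d.", message=msg,
        n_points=len(curve) if curve is not None else 0,
        assignment=curve.assignment if curve is not None else "",
        center=curve.center if curve is not None else np.nan,
    )


class CPDynamicsModel:
    """Nonlinear least-squares model for the CP build-up/decay curve.

    Parameters
    ----------
    curve : VCTCurve, or (contact_times_us, intensities) arrays via
        :meth:`from_arrays`.
    weighting : {"uniform", "relative"}
        ``uniform`` minimizes raw residuals; ``relative`` divides each
        residual by ``max(|y|, 1e-3 * max|y|)``, equalizing fractional error
        across the large dynamic range of a log-spaced contact grid.

    The optimizer is bounded derivative-based least squares with the analytic
    Jacobian of the model; on non-convergence three perturbed restarts of the
    automatic initialization are tried.
    """

    #: bounds on (S0, TCH_us, T1rhoH_us); S0 upper set per-curve
    TCH_BOUNDS = config.TCH_BOUNDS_US
    T1RHO_BOUNDS_US = (config.T1RHO_BOUNDS_MS[0] * _MS_TO_US,
                       config.T1RHO_BOUNDS_MS[1] * _MS_TO_US)

    def __init__(self, curve: VCTCurve, weighting: str = "uniform"):
        if weighting not in ("uniform", "relative"):
            raise ContractError(f"unknown weighting {weighting!r}")
        self.curve = curve
        self.weighting = weighting
        self.tc = curve.contact_times
        self.y = curve.intensities
        if self.weighting == "relative":
            ymax = float(np.max(np.abs(self.y))) or 1.0
            self._w = 1.0 / np.maximum(np.abs(self.y), 1e-3 * ymax)
        else:
            self._w = np.ones_like(self.y)

    @classmethod
    def from_arrays(cls, contact_times_us, intensities,
                    assignment: str = "", center: float = np.nan,
                    **kw) -> "CPDynamicsModel":
        return cls(VCTCurve(assignment, center,
                            np.asarray(contact_times_us, float),
                            np.asarray(intensities, float)), **kw)

    # -- internals ----------------------------------------------------------

    def _model(self, p):
        S0, tch, t1r = p
        return S0 * (1.0 - np.exp(-self.tc / tch)) * np.exp(-self.tc / t1r)

    def _residuals(self, p):
        return (self._model(p) - self.y) * self._w

    def _jacobian(self, p):
        S0, tch, t1r = p
        eb = np.exp(-self.tc / tch)     # build-up exponential
        ed = np.exp(-self.tc / t1r)     # decay exponential
        f = (1.0 - eb) * ed
        dS0 = f
        dtch = -S0 * ed * eb * self.tc / tch**2
        dt1r = S0 * (1.0 - eb) * ed * self.tc / t1r**2
        return np.column_stack([dS0, dtch, dt1r]) * self._w[:, None]

    def auto_init(self) -> np.ndarray:
        """Heuristic start: S0 from the curve maximum, TCH from the time to
        half-maximum on the rising limb (first crossing in time order),
        T1rhoH from the log-linear slope of the tail after the maximum."""
        y, tc = self.y, self.tc
        imax = int(np.argmax(y))
        s0 = 1.1 * y[imax]
        # rising limb half-max: first crossing in time order
        half = 0.5 * y[imax]
        rising = np.nonzero(y[: imax + 1] >= half)[0]
        tch = tc[rising[0]] if len(rising) else tc[max(imax // 2, 0)]
        tch = float(np.clip(tch, *self.TCH_BOUNDS))
        # tail: ln(S) regression after the maximum
        tail = np.arange(imax + 1, len(y))
        tail = tail[y[tail] > 0]
        if len(tail) >= 2:
            slope = np.polyfit(tc[tail], np.log(y[tail]), 1)[0]
            t1r = -1.0 / slope if slope < 0 else self.T1RHO_BOUNDS_US[1] / 10
        else:
            t1r = 10.0 * tc[imax]
        t1r = float(np.clip(t1r, *self.T1RHO_BOUNDS_US))
        return np.array([s0, tch, t1r])

    # -- fitting ------------------------------------------------------------

    def fit(self, init="auto") -> CPDynamicsResults:
        """Fit (S0, TCH, T1rhoH); returns a results object, never raises for
        data pathologies (they map to status ``n.d.``).

        ``init`` is ``"auto"`` or an explicit ``(S0, TCH_us, T1rhoH_ms)``
        triple.
        """
        curve = self.curve
        if curve.contaminated:
            return _nd(curve, "overlap-contaminated curve; pass force=True "
                              "via fit_cp_dynamics to fit anyway")
        if len(curve) < 5:
            return _nd(curve, f"only {len(curve)} points; >= 5 required")
        if not np.any(self.y > 0):
            return _nd(curve, "no positive intensities")

        if isinstance(init, str) and init == "auto":
            x0 = self.auto_init()
        else:
            s0, tch, t1r_ms = init
            x0 = np.array([s0, tch, t1r_ms * _MS_TO_US])

        s0_hi = 100.0 * float(np.max(np.abs(self.y)))
        lb = np.array([0.0, self.TCH_BOUNDS[0], self.T1RHO_BOUNDS_US[0]])
        ub = np.array([s0_hi, self.TCH_BOUNDS[1], self.T1RHO_BOUNDS_US[1]])
        x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)

        starts = [x0]
        # deterministic perturbed restarts used only on non-convergence
        for fac in ((0.5, 0.5, 2.0), (2.0, 2.0, 0.5), (1.0, 0.25, 4.0)):
            starts.append(np.clip(x0 * np.asarray(fac), lb + 1e-12,
                                  ub - 1e-12))

        best = None
        for k, start in enumerate(starts):
            try:
                res = least_squares(
                    self._residuals, start, jac=self._jacobian,
                    bounds=(lb, ub), method="trf", x_scale="jac",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
                )
            except Exception:  # numerical failure on this start
                continue
            if best is None or res.cost < best.cost:
                best = res
            if k == 0 and res.success and res.cost < 1e-30:
                break  # exact fit from the primary start
            if k == 0 and res.success:
                break
        if best is None or not best.success:
            return _nd(curve, "optimizer did not converge from any start")

        p = best.x
        n, k = len(self.y), 3
        sse = float(np.sum((self._model(p) - self.y) ** 2))
        sst = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else np.nan

        # asymptotic covariance from the Jacobian at the optimum
        J = self._jacobian(p)
        dof = max(n - k, 1)
        s2 = 2.0 * best.cost / dof
        try:
            cov_w = np.linalg.pinv(J.T @ J) * s2
        except np.linalg.LinAlgError:
            cov_w = np.full((3, 3), np.nan)
        # report T1rho in ms: scale row/col of the us-based covariance
        scale = np.diag([1.0, 1.0, 1.0 / _MS_TO_US])
        cov = scale @ cov_w @ scale
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

        t1r_ms = p[2] / _MS_TO_US
        status = "ok"
        msg = ""
        if not np.all(np.isfinite(cov)):
            status = "n.d."
            msg = "singular covariance"
        elif t1r_ms >= 0.99 * config.T1RHO_BOUNDS_MS[1]:
            status = "poor_fit"
            msg = "T1rhoH at upper bound; decay not observed in window"
        elif se[2] >= abs(t1r_ms):
            status = "n.d."
            msg = "relative se(T1rhoH) >= 100%"

        return CPDynamicsResults(
            S0=float(p[0]), S0_se=float(se[0]),
            TCH_us=float(p[1]), TCH_se=float(se[1]),
            T1rhoH_ms=float(t1r_ms), T1rhoH_se=float(se[2]),
            covariance=cov, r_squared=r2, n_points=n,
            converged=True, status=status, message=msg,
            assignment=curve.assignment, center=curve.center,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def extract_vct_curve(
    series: list[specmodel.Spectrum],
    peak: specmodel.Peak,
    readout_mode: str = "area",
) -> VCTCurve:
    """Read one peak's intensity across a contact-time series.

    Every spectrum must carry ``contact_time`` metadata and contain the peak
    window. Overlap-flagged peaks yield a curve marked contaminated, which
    downstream fitting reports as n.d. unless explicitly forced.
    """
    if not series:
        raise ContractError("empty spectrum series")
    tcs, vals = [], []
    for spec in series:
        tc = spec.meta.get("contact_time")
        if tc is None:
            raise ContractError("spectrum missing contact_time metadata")
        tcs.append(float(tc))
        vals.append(specmodel.integrate_peak(spec, peak, mode=readout_mode))
    order = np.argsort(tcs)
    return VCTCurve(
        assignment=peak.assignment,
        center=peak.center,
        contact_times=np.asarray(tcs)[order],
        intensities=np.asarray(vals)[order],
        readout_mode=readout_mode,
        contaminated=peak.overlap_group is not None,
    )


def fit_cp_dynamics(
    curve: VCTCurve,
    init="auto",
    weighting: str = "uniform",
    force: bool = False,
) -> CPFit:
    """Fit the CP dynamics curve; thin wrapper over :class:`CPDynamicsModel`.

    ``force=True`` fits an overlap-contaminated curve anyway (the default
    mirrors relaxation tables, where overlapped signals are n.d.).
    """
    if force and curve.contaminated:
        curve = replace(curve, contaminated=False)
    return CPDynamicsModel(curve, weighting=weighting).fit(init=init)


def fit_sample_table(
    series: list[specmodel.Spectrum],
    table: specmodel.PeakTable,
    readout_mode: str = "area",
    weighting: str = "uniform",
) -> list[tuple[specmodel.Peak, CPFit]]:
    """Extract and fit every peak of a table against one VCT series.

    Per-peak failures become status ``n.d.`` entries; the table never aborts
    as a whole. Output order follows the input table.
    """
    if not series:
        raise ContractError("empty spectrum series")
    if len(table) == 0:
        raise ContractError("empty peak table")
    out = []
    for peak in table:
        try:
            curve = extract_vct_curve(series, peak, readout_mode=readout_mode)
            fit = fit_cp_dynamics(curve, weighting=weighting)
        except Exception as exc:  # pragma: no cover - defensive per-peak guard
            fit = CPDynamicsResults(status="n.d.", message=str(exc),
                                    assignment=peak.assignment,
                                    center=peak.center)
        out.append((peak, fit))
    return out
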