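"""Electronic-tongue analytics and dissolution-release kinetics.

An impedimetric electronic tongue fingerprints a liquid through the |Z|(f)
responses of an array of chemically distinct sensing units; taste-masking
efficiency is read off the geometry of the resulting pattern space: how far
the resinate's cluster sits from the pure drug's relative to the resin's
("global selectivity"). This module builds the feature matrix from labelled
impedance spectra, projects it to 2-D (a documented Fastmap-initialized
force scheme, or classical metric MDS), scores cluster separation with the
silhouette coefficient, runs hierarchical clustering with Euclidean
distances, and fits single-exponential release kinetics to dissolution
traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform

from .errors import ContractError

__all__ = [
    "ImpedanceSpectrum",
    "ImpedanceSet",
    "ProjectionResult",
    "DissolutionCurve",
    "ReleaseModel",
    "ReleaseResults",
    "ReleaseFit",
    "feature_matrix",
    "project_2d",
    "silhouette_coefficient",
    "hca_distances",
    "HCAResult",
    "fit_release",
]

LN20 = float(np.log(20.0))  # t95 = tau * ln 20


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImpedanceSpectrum:
    """|Z|(f) of one sensing unit for one labelled sample replicate."""

    frequencies: np.ndarray  # Hz, strictly increasing
    magnitude: np.ndarray    # ohm, > 0
    class_label: str
    sensing_unit: str
    replicate: int

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.magnitude, dtype=float)
        if len(f) != len(z):
            raise ContractError("frequencies and magnitude lengths differ")
        if not np.all(np.diff(f) > 0):
            raise ContractError("frequencies must be strictly increasing")
        if np.any(z <= 0):
            raise ContractError("|Z| must be > 0 everywhere")
        self.frequencies = f
        self.magnitude = z


@dataclass
class ImpedanceSet:
    """Labelled impedance spectra sharing one frequency grid."""

    spectra: list[ImpedanceSpectrum]
    units: list[str]

    def __post_init__(self):
        seen = set()
        for s in self.spectra:
            key = (s.class_label, s.sensing_unit, s.replicate)
            if key in seen:
                raise ContractError(f"duplicate spectrum {key}")
            seen.add(key)
        grids = {tuple(s.frequencies) for s in self.spectra}
        if len(grids) > 1:
            raise ContractError("all spectra must share one frequency grid")

    @property
    def classes(self) -> list[str]:
        out = []
        for s in self.spectra:
            if s.class_label not in out:
                out.append(s.class_label)
        return out

    @property
    def replicates(self) -> list[int]:
        return sorted({s.replicate for s in self.spectra})


@dataclass
class ProjectionResult:
    """2-D projection of the e-tongue feature matrix."""

    coords: np.ndarray             # (n_samples, 2)
    labels: list[str]
    stress: float
    silhouette: float | None
    intercluster: pd.DataFrame     # class-centroid Euclidean distances, 2-D
    method: str
    degenerate: bool = False
    stress_history: list[float] = field(default_factory=list)

    def summary(self) -> str:
        sil = ("undefined" if self.silhouette is None
               else f"{self.silhouette:.4f}")
        lines = [
            f"2-D projection ({self.method})",
            f"samples: {len(self.labels)}   stress: {self.stress:.4g}   "
            f"silhouette: {sil}",
            "centroid distances:",
            self.intercluster.round(3).to_string(),
        ]
        return "\n".join(lines)


@dataclass
class DissolutionCurve:
    """Impedance-monitored release trace with its paired blank.

    The derived signal is ``|Z| - |Z0|`` pointwise by default (the
    conductivity-difference readout), or the ratio ``|Z| / |Z0|`` when
    ``signal_mode == "ratio"``.
    """

    time: np.ndarray      # s, strictly increasing
    Z_sample: np.ndarray  # ohm
    Z_blank: np.ndarray   # ohm
    signal_mode: str = "difference"
    warning: str | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        zs = np.asarray(self.Z_sample, dtype=float)
        zb = np.asarray(self.Z_blank, dtype=float)
        if not (len(t) == len(zs) == len(zb)):
            raise ContractError("time/Z_sample/Z_blank lengths differ")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ContractError("time must be strictly increasing")
        self.time, self.Z_sample, self.Z_blank = t, zs, zb

    @property
    def signal(self) -> np.ndarray:
        if self.signal_mode == "difference":
            return self.Z_sample - self.Z_blank
        if self.signal_mode == "ratio":
            return self.Z_sample / self.Z_blank
        raise ContractError(f"unknown signal_mode {self.signal_mode!r}")


@dataclass
class ReleaseResults:
    """Single-exponential release fit: s(t) = baseline + amplitude*(1-e^(-t/tau)).

    ``t95 = tau * ln 20`` is the time to 95% of the asymptotic change, the
    release-time figure this package reports.
    """

    tau: float = np.nan          # s
    tau_se: float = np.nan
    amplitude: float = np.nan    # ohm (difference mode)
    baseline: float = np.nan
    r_squared: float = np.nan
    n_points: int = 0
    converged: bool = False
    message: str = ""

    @property
    def t95(self) -> float:
        return self.tau * LN20

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.baseline + self.amplitude * (1.0 - np.exp(-t / self.tau))

    def summary(self) -> str:
        return "\n".join([
            "Exponential release fit",
            "=" * 46,
            f"converged: {self.converged}   n={self.n_points}   "
            f"R^2={self.r_squared:.5f}",
            f"tau       {self.tau:>12.4g} s   +/- {self.tau_se:.3g}",
            f"t95       {self.t95:>12.4g} s   ({self.t95 / 60.0:.2f} min)",
            f"amplitude {self.amplitude:>12.4g} ohm",
            f"baseline  {self.baseline:>12.4g} ohm",
            "=" * 46,
        ])


ReleaseFit = ReleaseResults


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def feature_matrix(
    iset: ImpedanceSet,
    normalize: str = "none",
) -> tuple[np.ndarray, list[str]]:
    """Samples-by-features matrix from an impedance set.

    One row per (class, replicate): the concatenation, unit-major and
    frequency-minor, of each sensing unit's log10|Z| vector. log-magnitudes
    are already commensurate across units and frequencies, so the default
    projects them as-is (the magnitude spectra themselves are the pattern);
    ``log_z_unitvar`` additionally standardizes each feature to zero mean,
    unit variance across samples — useful when units differ wildly in
    dynamic range, at the cost of amplifying features that carry only
    replicate noise. Returns (matrix, class labels per row).
    """
    if normalize not in ("log_z_unitvar", "none"):
        raise ContractError(f"unknown normalize {normalize!r}")
    by_key: dict[tuple[str, int], dict[str, ImpedanceSpectrum]] = {}
    for s in iset.spectra:
        by_key.setdefault((s.class_label, s.replicate), {})[s.sensing_unit] = s
    classes = iset.classes
    rows, labels = [], []
    for cls in classes:
        for rep in iset.replicates:
            units = by_key.get((cls, rep))
            if units is None:
                continue
            if set(units) != set(iset.units):
                raise ContractError(
                    f"sample ({cls}, {rep}) missing sensing units"
                )
            vec = np.concatenate(
                [np.log10(units[u].magnitude) for u in iset.units]
            )
            rows.append(vec)
            labels.append(cls)
    X = np.vstack(rows)
    if normalize == "log_z_unitvar":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X, labels


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def silhouette_coefficient(
    X: np.ndarray,
    labels,
    precomputed: bool = False,
) -> float:
    """Mean silhouette value over samples.

    For each sample, ``a`` is its mean distance to the other members of its
    class (self excluded) and ``b`` the smallest mean distance to any other
    class; the sample's silhouette is ``(b - a) / max(a, b)``. Members of
    singleton classes contribute 0 by convention. Euclidean distances unless
    ``precomputed`` marks ``X`` as a distance matrix.
    """
    labels = list(labels)
    X = np.asarray(X, dtype=float)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ContractError("silhouette needs >= 2 classes")
    D = X if precomputed else squareform(pdist(X, metric="euclidean"))
    n = len(labels)
    if D.shape != (n, n):
        raise ContractError("distance matrix does not match labels")
    idx = {c: np.array([i for i, l in enumerate(labels) if l == c])
           for c in classes}
    vals = np.zeros(n)
    for i in range(n):
        own = idx[labels[i]]
        if len(own) == 1:
            vals[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, idx[c]].mean() for c in classes if c != labels[i])
        m = max(a, b)
        vals[i] = 0.0 if m == 0 else (b - a) / m
    return float(vals.mean())


# ---------------------------------------------------------------------------
# 2-D projection
# ---------------------------------------------------------------------------

def _normalized_stress(D_target: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal-style normalized residual between target distances and the
    2-D configuration, with the optimal uniform scale applied to the 2-D
    distances (so the measure is invariant to the embedding's overall size).
    """
    d2 = pdist(coords)
    dt = squareform(D_target, checks=False)
    denom = float(np.sum(dt**2))
    if denom == 0:
        return 0.0
    s = float(np.dot(d2, dt) / np.sum(d2**2)) if np.any(d2 > 0) else 1.0
    return float(np.sqrt(np.sum((dt - s * d2) ** 2) / denom))


def _classical_mds(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    w2 = np.clip(w[order], 0.0, None)
    coords = V[:, order] * np.sqrt(w2)
    # deterministic sign convention
    for k in range(2):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords


def _fastmap_init(D: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two-axis Fastmap: pick farthest-pair pivots, project onto their line,
    repeat on the residual distances for the second axis."""
    n = D.shape[0]
    coords = np.zeros((n, 2))
    D2 = D.astype(float) ** 2
    for axis in range(2):
        a = int(rng.integers(n))
        for _ in range(3):  # heuristic farthest-pair refinement
            b = int(np.argmax(D2[a]))
            a2 = int(np.argmax(D2[b]))
            if a2 == a:
                break
            a = b if axis == 0 else a2
            a, b = a2, b
        dab2 = D2[a, b]
        if dab2 <= 0:
            break
        x = (D2[a] + dab2 - D2[b]) / (2.0 * np.sqrt(dab2))
        coords[:, axis] = x
        # residual squared distances for the next axis
        D2 = np.maximum(D2 - (x[:, None] - x[None, :]) ** 2, 0.0)
    return coords


def _force_scheme(
    D: np.ndarray,
    rng: np.random.Generator,
    n_sweeps: int = 50,
    step0: float = 0.3,
    step_final: float = 0.01,
) -> tuple[np.ndarray, list[float]]:
    """Fastmap-initialized iterative force placement.

    Each sweep visits every point in a seeded random order and moves every
    other point along their connecting line by a fraction of the residual
    (normalized data distance minus current 2-D distance); the fraction
    anneals geometrically from ``step0`` to ``step_final`` so early sweeps
    untangle the layout and late sweeps refine it. The best configuration by
    normalized stress over all sweeps is returned, so the reported stress is
    never worse than the initial one.
    """
    n = D.shape[0]
    dmax = D.max()
    T = D / dmax if dmax > 0 else D  # normalized target distances
    coords = _fastmap_init(T, rng)
    spread = pdist(coords).max() if n > 1 else 0.0
    if spread > 0:
        coords /= spread
    else:
        coords = rng.normal(0.0, 1e-3, (n, 2))
    history = [_normalized_stress(T, coords)]
    best = coords.copy()
    best_stress = history[0]
    eps = 1e-9
    decay = (step_final / step0) ** (1.0 / max(n_sweeps - 1, 1))
    for sweep in range(n_sweeps):
        step = step0 * decay**sweep
        for i in rng.permutation(n):
            diff = coords - coords[i]
            d2 = np.sqrt((diff**2).sum(axis=1))
            d2[i] = 1.0
            err = T[i] - d2
            move = step * (err / np.maximum(d2, eps))[:, None] * diff
            move[i] = 0.0
            coords += move
        s = _normalized_stress(T, coords)
        history.append(s)
        if s < best_stress:
            best_stress = s
            best = coords.copy()
    return best, history


def project_2d(
    matrix: np.ndarray,
    labels=None,
    method: str = "force_scheme",
    seed: int = 0,
    n_sweeps: int = 50,
) -> ProjectionResult:
    """Project a feature matrix to 2-D and score the class geometry.

    ``force_scheme`` is a Fastmap-initialized iterative force placement
    (points move toward/away from each other proportionally to the gap
    between normalized data-space distance and current 2-D distance);
    ``mds`` is classical metric scaling on Euclidean distances. The result
    carries the normalized stress, the silhouette of the class labels on the
    2-D coordinates, and the table of class-centroid Euclidean distances in
    the projection.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ContractError("need a 2-D matrix with >= 3 samples")
    labels = [str(i) for i in range(X.shape[0])] if labels is None \
        else list(labels)
    if len(labels) != X.shape[0]:
        raise ContractError("labels length must match sample count")
    D = squareform(pdist(X, metric="euclidean"))

    if D.max() == 0:  # degenerate: all rows identical
        coords = np.zeros((X.shape[0], 2))
        classes = sorted(set(labels))
        table = pd.DataFrame(0.0, index=classes, columns=classes)
        return ProjectionResult(coords, labels, 0.0, None, table,
                                method, degenerate=True)

    rng = np.random.default_rng(seed)
    history: list[float] = []
    if method == "mds":
        coords = _classical_mds(D)
    elif method == "force_scheme":
        coords, history = _force_scheme(D, rng, n_sweeps=n_sweeps)
    else:
        raise ContractError(f"unknown method {method!r}")

    dmax = D.max()
    stress = _normalized_stress(D / dmax, coords)
    classes = sorted(set(labels))
    sil = (silhouette_coefficient(coords, labels)
           if len(classes) >= 2 else None)
    cents = {c: coords[[i for i, l in enumerate(labels) if l == c]].mean(axis=0)
             for c in classes}
    table = pd.DataFrame(
        [[float(np.linalg.norm(cents[a] - cents[b])) for b in classes]
         for a in classes],
        index=classes, columns=classes,
    )
    return ProjectionResult(coords, labels, stress, sil, table, method,
                            stress_history=history)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class HCAResult:
    """Agglomerative merge tree plus class-centroid distances in data space."""

    merge_tree: np.ndarray          # scipy linkage matrix (heights in col 2)
    centroid_distances: pd.DataFrame | None
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merge_tree[:, 2]


def hca_distances(
    matrix: np.ndarray,
    labels=None,
    linkage: str = "average",
    metric: str = "euclidean",
) -> HCAResult:
    """Hierarchical agglomerative clustering with Euclidean distances.

    Returns the merge tree (dendrogram heights) and, when class labels are
    given, the symmetric table of class-centroid Euclidean distances.
    """
    if linkage not in ("average", "complete", "single"):
        raise ContractError(f"unsupported linkage {linkage!r}")
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ContractError("need >= 2 samples")
    Z = _scipy_linkage(X, method=linkage, metric=metric)
    table = None
    if labels is not None:
        labels = list(labels)
        classes = sorted(set(labels))
        cents = {c: X[[i for i, l in enumerate(labels) if l == c]].mean(axis=0)
                 for c in classes}
        table = pd.DataFrame(
            [[float(np.linalg.norm(cents[a] - cents[b])) for b in classes]
             for a in classes],
            index=classes, columns=classes,
        )
    return HCAResult(Z, table, linkage)


# ---------------------------------------------------------------------------
# release kinetics
# ---------------------------------------------------------------------------

class ReleaseModel:
    """Single-exponential release model fitted to a dissolution trace.

    The derived signal (impedance difference against the blank by default)
    is modelled as ``s(t) = baseline + amplitude * (1 - exp(-t / tau))`` and
    fitted by bounded nonlinear least squares with the analytic Jacobian.
    """

    def __init__(self, curve: DissolutionCurve):
        if len(curve.time) < 6:
            raise ContractError("need >= 6 time points")
        self.curve = curve
        self.t = curve.time
        self.s = curve.signal

    def _model(self, p):
        b, a, tau = p
        return b + a * (1.0 - np.exp(-self.t / tau))

    def _residuals(self, p):
        return self._model(p) - self.s

    def _jacobian(self, p):
        b, a, tau = p
        e = np.exp(-self.t / tau)
        return np.column_stack([
            np.ones_like(self.t),
            1.0 - e,
            -a * e * self.t / tau**2,
        ])

    def fit(self) -> ReleaseResults:
        s, t = self.s, self.t
        n = len(t)
        if np.allclose(s, s[0]):
            return ReleaseResults(n_points=n, converged=False,
                                  message="constant signal; nothing to fit")
        b0 = float(s[0])
        a0 = float(s[-1] - s[0]) or float(np.ptp(s))
        # time at ~63% of the total change as the tau start
        frac = (s - b0) / a0 if a0 != 0 else np.zeros_like(s)
        above = np.nonzero(frac >= 0.632)[0]
        tau0 = float(t[above[0]]) if len(above) and t[above[0]] > 0 \
            else float(t[-1] / 3.0)
        span = float(np.ptp(s))
        lb = [s.min() - 10 * span, -100 * span, t[1] * 1e-3]
        ub = [s.max() + 10 * span, 100 * span, t[-1] * 1e3]
        x0 = np.clip([b0, a0, tau0], np.array(lb) + 1e-12,
                     np.array(ub) - 1e-12)
        res = least_squares(self._residuals, x0, jac=self._jacobian,
                            bounds=(lb, ub), method="trf", x_scale="jac",
                            xtol=1e-13, ftol=1e-13, gtol=1e-13,
                            max_nfev=2000)
        if not res.success:
            return ReleaseResults(n_points=n, converged=False,
                                  message="optimizer did not converge")
        p = res.x
        sse = float(np.sum((self._model(p) - s) ** 2))
        sst = float(np.sum((s - s.mean()) ** 2))
        J = self._jacobian(p)
        dof = max(n - 3, 1)
        try:
            cov = np.linalg.pinv(J.T @ J) * (sse / dof)
            tau_se = float(np.sqrt(max(cov[2, 2], 0.0)))
        except np.linalg.LinAlgError:
            tau_se = np.nan
        return ReleaseResults(
            tau=float(p[2]), tau_se=tau_se,
            amplitude=float(p[1]), baseline=float(p[0]),
            r_squared=1.0 - sse / sst if sst > 0 else np.nan,
            n_points=n, converged=True,
        )


def fit_release(curve: DissolutionCurve) -> ReleaseResults:
    """Fit the exponential release law; wrapper over :class:`ReleaseModel`."""
    return ReleaseModel(curve).fit()
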