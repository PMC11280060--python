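"""Data model and I/O for 1-D solid-state NMR spectra and peak tables.

The objects here are deliberately plain: a :class:`Spectrum` is one frequency-
domain trace (ppm axis stored descending, the usual NMR display convention),
a :class:`Peak` is one assigned or unassigned resonance with an integration
window, and a :class:`PeakTable` is an ordered collection of peaks for one
sample. Operations cover referencing against a shift standard, peak picking,
peak integration (the signal readout of the variable-contact-time experiment)
and spinning-sideband bookkeeping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from . import config
from .errors import (
    ContractError,
    InvalidSpectrumError,
    OutOfRangeError,
    ParseError,
)

__all__ = [
    "Spectrum",
    "Peak",
    "PeakTable",
    "load_spectrum",
    "save_spectrum",
    "reference_shift",
    "pick_peaks",
    "integrate_peak",
    "flag_sidebands",
    "load_peak_table",
    "save_peak_table",
    "assign_peaks",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """A 1-D frequency-domain NMR spectrum.

    Parameters
    ----------
    ppm_axis : array-like
        Chemical-shift axis in ppm, strictly monotone. Stored descending;
        ascending input is flipped together with the intensities.
    intensity : array-like
        Signal values (arbitrary units), same length as the axis.
    meta : dict
        Free-form acquisition metadata. Recognized keys include
        ``field_strength`` (T), ``larmor_freq`` (MHz), ``spin_rate`` (Hz),
        ``contact_time`` (us), ``recycle_delay`` (s), ``nucleus`` and
        ``sample_id``. Absent keys stay absent; nothing is defaulted.
    """

    ppm_axis: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ppm = np.asarray(self.ppm_axis, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or inten.ndim != 1 or len(ppm) != len(inten):
            raise InvalidSpectrumError(
                "ppm_axis and intensity must be 1-D and of equal length"
            )
        if len(ppm) < 2:
            raise InvalidSpectrumError("a spectrum needs at least 2 points")
        d = np.diff(ppm)
        if np.all(d > 0):  # ascending input: flip to display order
            ppm, inten = ppm[::-1], inten[::-1]
        elif not np.all(d < 0):
            raise InvalidSpectrumError("ppm axis must be strictly monotone")
        self.ppm_axis = ppm
        self.intensity = inten
        ct = self.meta.get("contact_time")
        if ct is not None and ct <= 0:
            raise ContractError("contact_time must be > 0 when present")
        sr = self.meta.get("spin_rate")
        if sr is not None and sr < 0:
            raise ContractError("spin_rate must be >= 0")

    def __len__(self) -> int:
        return len(self.ppm_axis)

    @property
    def larmor_freq(self) -> float | None:
        """Larmor frequency in MHz; derived from field strength if needed."""
        lf = self.meta.get("larmor_freq")
        if lf is not None:
            return float(lf)
        b0 = self.meta.get("field_strength")
        if b0 is not None:
            return float(b0) * config.GAMMA_13C_MHZ_PER_T
        return None

    def axis_step(self) -> float:
        """Median spacing of the ppm axis (positive)."""
        return float(np.median(np.abs(np.diff(self.ppm_axis))))


@dataclass
class Peak:
    """One resonance: a center, an integration window, and bookkeeping flags.

    ``height`` is an optional observed intensity at the center (filled in by
    :func:`pick_peaks`); it is what sideband flagging uses to decide which
    peak of a family is the isotropic (strongest) one.
    """

    center: float
    assignment: str = ""
    window: tuple[float, float] = (0.0, 0.0)
    is_sideband: bool = False
    sideband_order: int = 0
    overlap_group: str | None = None
    height: float | None = None
    component: str | None = None  # {"drug", "resin"} when known

    def __post_init__(self):
        lo, hi = self.window
        if lo >= hi:
            raise ContractError(f"window lo {lo} must be < hi {hi}")
        if not (lo <= self.center <= hi):
            raise ContractError(
                f"center {self.center} outside window ({lo}, {hi})"
            )
        if self.is_sideband != (self.sideband_order != 0):
            raise ContractError("sideband_order == 0 iff not is_sideband")


@dataclass
class PeakTable:
    """Ordered peak list for one sample. Duplicate assignments (unfolded
    signals) are permitted; windows of non-overlap peaks must be disjoint."""

    peaks: list[Peak]
    sample_id: str = ""

    def __post_init__(self):
        clean = [p for p in self.peaks if p.overlap_group is None]
        wins = sorted(p.window for p in clean)
        for (lo1, hi1), (lo2, hi2) in zip(wins, wins[1:]):
            if lo2 < hi1:
                raise ContractError(
                    f"windows ({lo1},{hi1}) and ({lo2},{hi2}) overlap"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_assignment(self, assignment: str) -> list[Peak]:
        return [p for p in self.peaks if p.assignment == assignment]

    @property
    def assignments(self) -> list[str]:
        return [p.assignment for p in self.peaks]

    def _with_peaks(self, peaks: list[Peak]) -> "PeakTable":
        # bypass the disjoint-window check: used by transforms that only
        # change flags/assignments on already-validated windows
        out = PeakTable.__new__(PeakTable)
        out.peaks = peaks
        out.sample_id = self.sample_id
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"^#\s*([\w.]+)\s*:\s*(.+?)\s*$")
_NUMERIC_META = {
    "field_strength", "larmor_freq", "spin_rate", "contact_time",
    "recycle_delay", "reference_offset_ppm",
}


def _parse_csv(path) -> Spectrum:
    ppm, inten, meta = [], [], {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _META_RE.match(line)
            if m:
                key, val = m.group(1), m.group(2)
                try:
                    meta[key] = float(val) if key in _NUMERIC_META else val
                except ValueError:
                    raise ParseError(f"bad metadata value {val!r}", lineno)
                continue
            if line.startswith("#"):
                continue
            parts = [p for p in re.split(r"[,\s]+", line) if p]
            if parts and parts[0].lower() in ("ppm", "ppm_axis"):
                continue  # header row
            if len(parts) < 2:
                raise ParseError(f"expected two columns, got {line!r}", lineno)
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"non-numeric value in {line!r}", lineno)
            ppm.append(x)
            inten.append(y)
    if len(ppm) < 2:
        raise InvalidSpectrumError(f"{path}: fewer than 2 data points")
    return Spectrum(np.array(ppm), np.array(inten), meta)


def _parse_jcamp(path) -> Spectrum:
    """Minimal single-block JCAMP-DX reader: ##XYDATA=(X++(Y..Y)) with
    FIRSTX/LASTX/NPOINTS/YFACTOR headers, AFFN (plain decimal) values only."""
    headers: dict[str, str] = {}
    yvals: list[float] = []
    in_xy = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XYDATA":
                    in_xy = True
                    continue
                if key == "END":
                    break
                headers[key] = val
                in_xy = False
                continue
            if in_xy:
                parts = line.replace(",", " ").split()
                try:
                    vals = [float(p) for p in parts]
                except ValueError:
                    raise ParseError(f"non-numeric XYDATA in {line!r}", lineno)
                yvals.extend(vals[1:])  # first token is the running X
    try:
        firstx = float(headers["FIRSTX"])
        lastx = float(headers["LASTX"])
        npoints = int(float(headers["NPOINTS"]))
    except KeyError as exc:
        raise ParseError(f"missing JCAMP header ##{exc.args[0]}")
    yfactor = float(headers.get("YFACTOR", 1.0))
    if len(yvals) != npoints:
        raise ParseError(f"NPOINTS={npoints} but {len(yvals)} Y values read")
    x = np.linspace(firstx, lastx, npoints)
    meta = {}
    if "TITLE" in headers:
        meta["sample_id"] = headers["TITLE"]
    if ".OBSERVEFREQUENCY" in headers:
        meta["larmor_freq"] = float(headers[".OBSERVEFREQUENCY"])
    return Spectrum(x, np.array(yvals) * yfactor, meta)


def load_spectrum(path, dialect: str = "csv") -> Spectrum:
    """Read a spectrum from two-column CSV or single-block JCAMP-DX text.

    CSV rows are ``ppm,intensity`` with optional ``# key: value`` metadata
    header lines. The returned axis is sorted descending regardless of file
    order; missing metadata stays absent.
    """
    if dialect == "csv":
        return _parse_csv(path)
    if dialect == "jcamp":
        return _parse_jcamp(path)
    raise ContractError(f"unknown dialect {dialect!r}")


def save_spectrum(spec: Spectrum, path) -> None:
    """Write a spectrum in the CSV dialect :func:`load_spectrum` reads."""
    with open(path, "w") as fh:
        for key, val in spec.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("ppm,intensity\n")
        for x, y in zip(spec.ppm_axis, spec.intensity):
            fh.write(f"{x:.6f},{y:.10g}\n")


def load_peak_table(path, sample_id: str = "") -> PeakTable:
    """Read ``assignment,center_ppm,window_lo,window_hi[,overlap_group]``
    delimited text (standard CSV quoting; assignments may contain commas)."""
    import csv as _csv

    peaks = []
    with open(path, newline="") as fh:
        for lineno, parts in enumerate(_csv.reader(fh), start=1):
            if not parts or not parts[0].strip() \
                    or parts[0].lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in parts]
            if parts[0].lower() == "assignment":
                continue
            if len(parts) < 4:
                raise ParseError(f"expected 4 columns, got {parts!r}", lineno)
            try:
                center, lo, hi = (float(v) for v in parts[1:4])
            except ValueError:
                raise ParseError(f"non-numeric value in {parts!r}", lineno)
            overlap = parts[4] if len(parts) > 4 and parts[4] else None
            component = parts[5] if len(parts) > 5 and parts[5] else None
            peaks.append(Peak(center, parts[0], (lo, hi),
                              overlap_group=overlap, component=component))
    return PeakTable(peaks, sample_id=sample_id)


def save_peak_table(table: PeakTable, path) -> None:
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["assignment", "center_ppm", "window_lo", "window_hi",
                    "overlap_group", "component"])
        for p in table:
            w.writerow([p.assignment, f"{p.center:.4f}",
                        f"{p.window[0]:.4f}", f"{p.window[1]:.4f}",
                        p.overlap_group or "", p.component or ""])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def reference_shift(
    spec: Spectrum,
    observed_ref: float,
    true_ref: float = config.GLYCINE_CO_PPM,
) -> Spectrum:
    """Reference the chemical-shift axis against a standard.

    The whole axis is translated by ``true_ref - observed_ref`` so that the
    line observed at ``observed_ref`` reads ``true_ref`` (glycine carbonyl at
    176.03 ppm by default). Intensities are untouched; the applied offset is
    recorded in metadata. Referencing is an exact translation, so all pairwise
    ppm differences are preserved.
    """
    lo, hi = spec.ppm_axis[-1], spec.ppm_axis[0]
    if not (lo <= observed_ref <= hi):
        raise OutOfRangeError(
            f"observed_ref {observed_ref} outside axis range [{lo}, {hi}]"
        )
    offset = true_ref - observed_ref
    meta = dict(spec.meta)
    meta["reference_offset_ppm"] = meta.get("reference_offset_ppm", 0.0) + offset
    return Spectrum(spec.ppm_axis + offset, spec.intensity.copy(), meta)


def pick_peaks(
    spec: Spectrum,
    min_prominence: float = 0.05,
    min_separation: float = 0.5,
) -> PeakTable:
    """Detect local maxima, greedily enforcing a minimum ppm separation.

    ``min_prominence`` is a fraction of the maximum intensity. When two lines
    fall closer than ``min_separation`` only the taller is reported. Windows
    are set to the nearest flanking local minima. Assignments are left empty;
    join against a reference table with :func:`assign_peaks`. A flat spectrum
    yields an empty table, not an error.
    """
    if not (0 < min_prominence < 1):
        raise ContractError("min_prominence must be in (0, 1)")
    if min_separation <= 0:
        raise ContractError("min_separation must be > 0")
    y = spec.intensity
    ymax = float(y.max())
    if ymax <= 0 or np.allclose(y, y[0]):
        return PeakTable([], sample_id=spec.meta.get("sample_id", ""))
    idx, _ = find_peaks(y, prominence=min_prominence * ymax)
    if len(idx) == 0:
        return PeakTable([], sample_id=spec.meta.get("sample_id", ""))
    # greedy: tallest first, suppress neighbours closer than min_separation
    order = idx[np.argsort(y[idx])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(abs(spec.ppm_axis[i] - spec.ppm_axis[j]) >= min_separation
               for j in kept):
            kept.append(int(i))
    kept.sort()
    # windows at nearest flanking local minima around each kept maximum
    minima, _ = find_peaks(-y)
    minima = np.concatenate(([0], minima, [len(y) - 1]))
    peaks = []
    for i in kept:
        il = int(minima[minima < i][-1])
        ir = int(minima[minima > i][0])
        lo = min(spec.ppm_axis[il], spec.ppm_axis[ir])
        hi = max(spec.ppm_axis[il], spec.ppm_axis[ir])
        peaks.append(Peak(float(spec.ppm_axis[i]), "", (lo, hi),
                          height=float(y[i])))
    peaks.sort(key=lambda p: -p.center)  # descending ppm, display order
    table = PeakTable.__new__(PeakTable)
    table.peaks = peaks
    table.sample_id = spec.meta.get("sample_id", "")
    return table


def integrate_peak(spec: Spectrum, peak: Peak, mode: str = "area") -> float:
    """Signal readout over a peak window.

    ``area`` is the trapezoidal integral over the window (ppm x intensity
    units, positive for positive signal); ``height`` is the maximum intensity
    in the window. Deterministic, linear in intensity scaling, and (for area)
    additive over disjoint windows.
    """
    lo, hi = peak.window
    axis_lo, axis_hi = spec.ppm_axis[-1], spec.ppm_axis[0]
    if lo < axis_lo or hi > axis_hi:
        raise OutOfRangeError(
            f"window ({lo}, {hi}) outside axis [{axis_lo}, {axis_hi}]"
        )
    mask = (spec.ppm_axis >= lo) & (spec.ppm_axis <= hi)
    if not mask.any():
        raise OutOfRangeError(f"no axis points inside window ({lo}, {hi})")
    y = spec.intensity[mask]
    if mode == "height":
        return float(y.max())
    if mode == "area":
        x = spec.ppm_axis[mask]
        # axis is descending; integrate the ascending copy
        return float(np.trapezoid(y[::-1], x[::-1]))
    raise ContractError(f"unknown mode {mode!r}")


def flag_sidebands(
    table: PeakTable,
    spin_rate: float,
    larmor: float,
    max_order: int = 2,
    tol_ppm: float = 1.0,
) -> PeakTable:
    """Flag spinning sidebands by ppm spacing from a stronger peak.

    Under magic-angle spinning at ``spin_rate`` Hz observed at ``larmor`` MHz,
    sidebands appear displaced from an isotropic line by multiples of
    ``spin_rate / larmor`` ppm (97.4 ppm at 9800 Hz / 100.61 MHz). Any peak
    whose center lies within ``tol_ppm`` of ``iso + k * spacing`` (signed
    ``k``, ``1 <= |k| <= max_order``) of a *stronger* peak is flagged with
    that order. Strength is ``Peak.height`` when present (as set by
    :func:`pick_peaks`); peaks of unknown height never act as sidebands nor
    anchors against known-height peaks of equal rank. Flagging is idempotent
    and never flags the strongest peak of a family; with no candidates the
    table is returned unchanged.
    """
    if spin_rate <= 0 or larmor <= 0:
        raise ContractError("spin_rate and larmor must be > 0")
    spacing = spin_rate / larmor  # ppm

    def strength(p: Peak) -> float:
        return p.height if p.height is not None else 0.0

    peaks = [replace(p) for p in table.peaks]
    out: list[Peak] = []
    for cand in peaks:
        if cand.is_sideband:
            out.append(cand)
            continue
        order_found = 0
        for iso in peaks:
            if iso is cand or iso.is_sideband:
                continue
            if not strength(iso) > strength(cand):
                continue
            for k in range(1, max_order + 1):
                if abs(cand.center - (iso.center + k * spacing)) <= tol_ppm:
                    order_found = k
                    break
                if abs(cand.center - (iso.center - k * spacing)) <= tol_ppm:
                    order_found = -k
                    break
            if order_found:
                break
        if order_found:
            out.append(replace(cand, is_sideband=True,
                               sideband_order=order_found))
        else:
            out.append(cand)
    return table._with_peaks(out)


def assign_peaks(
    picked: PeakTable,
    reference: PeakTable,
    gate_ppm: float = config.ASSIGNMENT_MATCH_GATE_PPM,
) -> PeakTable:
    """Join picked peaks to reference assignments by nearest center.

    Each picked peak takes the assignment (and overlap flag) of the nearest
    reference peak within ``gate_ppm``; unmatched peaks keep an empty
    assignment.
    """
    out = []
    for p in picked:
        best, best_d = None, gate_ppm
        for r in reference:
            d = abs(p.center - r.center)
            if d <= best_d:
                best, best_d = r, d
        if best is not None:
            out.append(replace(p, assignment=best.assignment,
                               overlap_group=best.overlap_group))
        else:
            out.append(replace(p))
    return picked._with_peaks(out)
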