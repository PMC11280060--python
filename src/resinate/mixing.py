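"""Mixing-state inference: shift changes, splitting, and the T1rhoH verdict.

Whether a drug and an ion-exchange resin form a true molecular-scale complex
or merely a physical mixture is decided from two solid-state NMR observables:

* chemical-shift perturbation — complexation shifts and splits the drug's
  carbon resonances, while a physical mixture leaves both components'
  spectra superposed but unchanged;
* proton rotating-frame relaxation — proton spin diffusion homogenizes
  T1rhoH over domains of a few nanometers, so in an intimate complex the
  drug carbons inherit resin-like (short) T1rhoH values, whereas in a
  physical mixture each component keeps its own.

``classify_mixing`` turns the second observation into an explicit rule with
two configurable ratios: the drug's median T1rhoH must drop at least
``reduction_factor``-fold from the pure drug AND converge to within
``convergence_factor`` of the resin's for a ``complex`` verdict; both
components retaining their pure-phase values (within ``reduction_factor``)
gives ``physical_mixture``; anything else is ``indeterminate``.

Medians (not means) aggregate across carbons — robust to single outlying
fits. Also here: drug-loading efficiency from bound vs unbound drug mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import config
from .errors import ContractError
from .specmodel import PeakTable

__all__ = [
    "ShiftComparison",
    "MixingReport",
    "delta_shifts",
    "detect_splitting",
    "classify_mixing",
    "drug_loading_efficiency",
]


# ---------------------------------------------------------------------------
# chemical-shift comparison
# ---------------------------------------------------------------------------

@dataclass
class ShiftComparison:
    """Per-carbon shift change between a reference sample and the complex.

    ``delta_shift = delta_complex - delta_ref``; positive means deshielded
    (moved to higher frequency). ``classification`` is ``unchanged`` when
    |delta| does not exceed the threshold, ``deshielded``/``shielded``
    beyond it, ``split`` when the complex shows more components than the
    reference, ``overlap`` when the complex signal is buried under the other
    component, and ``new`` for complex-only signals.
    """

    assignment: str
    delta_ref: float | None
    delta_complex: float | None
    delta_shift: float | None
    classification: str


def _paired(ref_peaks, cpx_peaks):
    """Order-preserving pairing of two descending-sorted shift lists.

    With equal multiplicities the k-th strongest-field component pairs with
    the k-th (no crossings); otherwise each reference entry takes the
    nearest unused complex entry, scanned in descending order.
    """
    ref_sorted = sorted(ref_peaks, key=lambda p: -p.center)
    cpx_sorted = sorted(cpx_peaks, key=lambda p: -p.center)
    if len(ref_sorted) == len(cpx_sorted):
        return list(zip(ref_sorted, cpx_sorted))
    pairs = []
    used = set()
    for r in ref_sorted:
        best, best_d = None, np.inf
        for j, c in enumerate(cpx_sorted):
            if j in used:
                continue
            d = abs(c.center - r.center)
            if d < best_d:
                best, best_d = j, d
        if best is not None:
            used.add(best)
            pairs.append((r, cpx_sorted[best]))
        else:
            pairs.append((r, None))
    return pairs


def delta_shifts(
    ref: PeakTable,
    complex_table: PeakTable,
    threshold: float = 1.0,
) -> list[ShiftComparison]:
    """Per-assignment shift changes, complex minus reference.

    One comparison per reference peak. Multi-component (unfolded) signals
    are paired order-preservingly within the assignment, so the k-th
    highest-frequency reference component compares against the k-th in the
    complex. The reference may be the solid pure-drug table or the solution
    (DMSO) shift table — the caller picks which reference frame to use.
    Assignments present only in the complex are appended as ``new``.
    """
    if threshold <= 0:
        raise ContractError("threshold must be > 0")
    out: list[ShiftComparison] = []
    ref_assigns = []
    for p in ref:
        if p.assignment and p.assignment not in ref_assigns:
            ref_assigns.append(p.assignment)
    for a in ref_assigns:
        rp = ref.by_assignment(a)
        cp = complex_table.by_assignment(a)
        overlap_cp = [p for p in cp if p.overlap_group is not None]
        clean_cp = [p for p in cp if p.overlap_group is None]
        if not cp:
            continue  # absent from the complex table: omitted
        if overlap_cp and not clean_cp:
            for r in rp:
                out.append(ShiftComparison(a, r.center, None, None,
                                           "overlap"))
            continue
        split = len(clean_cp) > len(rp)
        for r, c in _paired(rp, clean_cp):
            if c is None:
                out.append(ShiftComparison(a, r.center, None, None,
                                           "overlap" if overlap_cp
                                           else "unmatched"))
                continue
            d = c.center - r.center
            if split:
                cls = "split"
            elif abs(d) <= threshold:
                cls = "unchanged"
            else:
                cls = "deshielded" if d > 0 else "shielded"
            out.append(ShiftComparison(a, r.center, c.center, d, cls))
    for p in complex_table:
        if p.assignment and p.assignment not in ref_assigns:
            out.append(ShiftComparison(p.assignment, None, p.center, None,
                                       "new"))
    return out


def detect_splitting(
    ref: PeakTable,
    complex_table: PeakTable,
    window: float = 3.0,
) -> list[tuple[str, int, int]]:
    """Signal multiplicities per assignment, reference vs complex.

    For each reference assignment, counts the same-assignment peaks lying
    within ``+/- window`` ppm of the reference assignment's mean center in
    both tables. A (1, 3) entry flags a singlet that split into a triplet
    upon complexation.
    """
    if window <= 0:
        raise ContractError("window must be > 0")
    out = []
    seen = []
    for p in ref:
        if p.assignment and p.assignment not in seen:
            seen.append(p.assignment)
    for a in seen:
        centers = [p.center for p in ref.by_assignment(a)]
        c0 = float(np.mean(centers))
        n_ref = sum(1 for p in ref.by_assignment(a)
                    if abs(p.center - c0) <= window)
        n_cpx = sum(1 for p in complex_table.by_assignment(a)
                    if p.overlap_group is None and abs(p.center - c0) <= window)
        out.append((a, n_ref, n_cpx))
    return out


# ---------------------------------------------------------------------------
# T1rhoH spin-diffusion verdict
# ---------------------------------------------------------------------------

@dataclass
class MixingReport:
    """Verdict of the spin-diffusion mixing test with its evidence trail."""

    verdict: str                                   # complex | physical_mixture | indeterminate
    drug_T1rho: list[tuple[str, float]]            # usable sample drug fits, ms
    resin_T1rho: list[tuple[str, float]]           # usable sample resin fits, ms
    pure_drug_T1rho: list[tuple[str, float]]
    pure_resin_T1rho: list[tuple[str, float]]
    summary: dict = field(default_factory=dict)    # medians and ratios
    evidence: dict = field(default_factory=dict)   # per-rule booleans

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "summary": self.summary,
            "evidence": self.evidence,
            "drug_T1rho_ms": self.drug_T1rho,
            "resin_T1rho_ms": self.resin_T1rho,
            "pure_drug_T1rho_ms": self.pure_drug_T1rho,
            "pure_resin_T1rho_ms": self.pure_resin_T1rho,
        }

    def text_summary(self) -> str:
        s = self.summary
        lines = [
            f"mixing verdict: {self.verdict}",
            f"  median T1rhoH (ms): sample drug {s.get('median_drug_sample'):.3g}"
            if s.get("median_drug_sample") is not None else
            "  median T1rhoH (ms): sample drug n/a",
        ]
        if s.get("median_resin_sample") is not None:
            lines.append(f"                      sample resin "
                         f"{s['median_resin_sample']:.3g}")
        if s.get("median_pure_drug") is not None:
            lines.append(f"                      pure drug "
                         f"{s['median_pure_drug']:.3g}")
        if s.get("median_pure_resin") is not None:
            lines.append(f"                      pure resin "
                         f"{s['median_pure_resin']:.3g}")
        for rule, ok in self.evidence.items():
            lines.append(f"  [{'x' if ok else ' '}] {rule}")
        return "\n".join(lines)


def _usable(entries: Iterable) -> list[tuple[str, float]]:
    """Extract (assignment, T1rhoH ms) from CPFit-like objects or bare
    numbers; only fits with status 'ok' (or plain values) count."""
    out = []
    for i, e in enumerate(entries):
        if hasattr(e, "T1rhoH_ms"):
            if getattr(e, "status", "ok") == "ok" \
                    and np.isfinite(e.T1rhoH_ms):
                out.append((getattr(e, "assignment", "") or f"#{i}",
                            float(e.T1rhoH_ms)))
        elif isinstance(e, tuple) and len(e) == 2:
            out.append((str(e[0]), float(e[1])))
        else:
            out.append((f"#{i}", float(e)))
    return out


def classify_mixing(
    sample_fits,
    pure_drug_fits,
    pure_resin_fits,
    convergence_factor: float = config.CONVERGENCE_FACTOR,
    reduction_factor: float = config.REDUCTION_FACTOR,
) -> MixingReport:
    """Spin-diffusion verdict on one sample's fitted T1rhoH values.

    Parameters
    ----------
    sample_fits : iterable of (component, fit)
        ``component`` is ``"drug"`` or ``"resin"``; ``fit`` is a CP-dynamics
        result (only status-``ok`` fits are used), a bare T1rhoH value in
        ms, or an ``(assignment, value)`` pair.
    pure_drug_fits, pure_resin_fits : iterable
        Same element forms, for the pure components measured separately.
    convergence_factor, reduction_factor : float
        The two ratio thresholds of the rule (see module docstring).

    Returns an ``indeterminate`` report (never an error) when fewer than two
    usable drug fits exist in the sample.
    """
    if convergence_factor <= 0 or reduction_factor <= 0:
        raise ContractError("factors must be > 0")
    drug, resin = [], []
    for comp, fit in sample_fits:
        if comp == "drug":
            drug += _usable([fit])
        elif comp == "resin":
            resin += _usable([fit])
        else:
            raise ContractError(f"unknown component {comp!r}")
    pure_drug = _usable(pure_drug_fits)
    pure_resin = _usable(pure_resin_fits)

    med = lambda pairs: float(np.median([v for _, v in pairs])) if pairs \
        else None
    md_s, mr_s = med(drug), med(resin)
    md_p, mr_p = med(pure_drug), med(pure_resin)

    summary = {
        "median_drug_sample": md_s,
        "median_resin_sample": mr_s,
        "median_pure_drug": md_p,
        "median_pure_resin": mr_p,
        "n_drug_usable": len(drug),
        "n_resin_usable": len(resin),
    }
    if md_s is not None and md_p is not None:
        summary["reduction_ratio"] = md_p / md_s
    if md_s is not None and mr_s is not None:
        summary["convergence_ratio"] = md_s / mr_s

    evidence = {}
    if len(drug) < 2:
        evidence["enough_drug_fits"] = False
        return MixingReport("indeterminate", drug, resin, pure_drug,
                            pure_resin, summary, evidence)
    evidence["enough_drug_fits"] = True

    reduced = (md_p is not None
               and md_s <= md_p / reduction_factor)
    converged = (mr_s is not None
                 and md_s / mr_s <= convergence_factor)
    drug_unchanged = (md_p is not None
                      and md_p / reduction_factor <= md_s
                      <= md_p * reduction_factor)
    resin_unchanged = (mr_s is not None and mr_p is not None
                       and mr_p / reduction_factor <= mr_s
                       <= mr_p * reduction_factor)
    evidence["drug_T1rho_reduced"] = bool(reduced)
    evidence["drug_resin_T1rho_converged"] = bool(converged)
    evidence["drug_T1rho_unchanged"] = bool(drug_unchanged)
    evidence["resin_T1rho_unchanged"] = bool(resin_unchanged)

    if reduced and converged:
        verdict = "complex"
    elif drug_unchanged and resin_unchanged:
        verdict = "physical_mixture"
    else:
        verdict = "indeterminate"
    return MixingReport(verdict, drug, resin, pure_drug, pure_resin,
                        summary, evidence)


def classify_from_fits(
    sample_fits,
    pure_drug_fits,
    pure_resin_fits,
    convergence_factor: float = config.CONVERGENCE_FACTOR,
    reduction_factor: float = config.REDUCTION_FACTOR,
) -> MixingReport:
    """Round-trip convenience: verdict straight from per-peak fit tables.

    ``sample_fits`` is the (peak, fit) list produced by
    ``cpdyn.fit_sample_table`` on the sample under test, with each peak's
    ``component`` tag identifying drug vs resin carbons; the pure-component
    arguments are plain fit lists (or (peak, fit) lists) for the drug and
    resin measured separately.
    """
    def flatten(entries):
        return [e[1] if isinstance(e, tuple) else e for e in entries]

    sample = [(p.component, f) for p, f in sample_fits
              if getattr(p, "component", None) in ("drug", "resin")]
    return classify_mixing(sample, flatten(pure_drug_fits),
                           flatten(pure_resin_fits),
                           convergence_factor=convergence_factor,
                           reduction_factor=reduction_factor)


def drug_loading_efficiency(mass_total: float, mass_unbound: float) -> float:
    """Percent of drug bound to the resin:
    ``100 * (mass_total - mass_unbound) / mass_total``."""
    if mass_total <= 0:
        raise ContractError("mass_total must be > 0")
    if not (0 <= mass_unbound <= mass_total):
        raise ContractError("mass_unbound must lie in [0, mass_total]")
    return 100.0 * (mass_total - mass_unbound) / mass_total
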