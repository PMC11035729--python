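"""End-to-end signal screening: tables -> statistics -> exclusions -> reports.

The screening pipeline mirrors the workflow of a published FAERS
disproportionality study: enumerate one 2x2 table per observed preferred
term among cases exposed to the study drug, compute ROR/PRR/BCPNN, apply
the triple-positive signal rule, strike invalid terms via a user-supplied
exclusion list (terms with no reference value, disease-of-indication terms,
medication-error terms), and aggregate the surviving signals by system
organ class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .contingency import build_all_tables
from .disproportionality import (
    BcpnnPriors,
    DispropResult,
    SignalCriteria,
    compute_statistics,
    evaluate_signal,
)
from .io import CaseView, VocabularyMap, _key

EXCLUSION_CATEGORIES = ("non_reference", "disease_related", "medication_error")


@dataclass(frozen=True)
class ExclusionPolicy:
    """Preferred terms to strike from the signal set (never from output)."""

    excluded_pts: frozenset[str] = frozenset()
    categories: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_pts(cls, pts: Iterable[str],
                 categories: Mapping[str, str] | None = None) -> "ExclusionPolicy":
        cats = {}
        for pt, cat in (categories or {}).items():
            if cat not in EXCLUSION_CATEGORIES:
                raise ValueError(f"unknown exclusion category {cat!r}")
            cats[_key(pt)] = cat
        return cls(frozenset(_key(p) for p in pts), cats)

    def __contains__(self, pt: str) -> bool:
        return _key(pt) in self.excluded_pts


@dataclass(frozen=True)
class SocSummary:
    """Per-SOC tally over signal PTs: report sum and signal count."""

    soc: str
    n_reports: int
    n_signals: int


def run_screen(cases: Sequence[CaseView], drug: str,
               criteria: SignalCriteria | None = None,
               exclusions: ExclusionPolicy | None = None,
               vocab: VocabularyMap | None = None,
               priors: BcpnnPriors | None = None,
               min_a: int = 1) -> list[DispropResult]:
    """Screen every PT observed among *drug*-exposed cases.

    Returns one :class:`DispropResult` per enumerated PT, sorted by report
    count descending then PT ascending.  Excluded PTs keep their statistics
    and flags but are marked ``excluded`` so they leave the signal set
    without being dropped from the output.  When a vocabulary is given each
    result carries its SOC ("Unmapped" if absent).
    """
    criteria = criteria or SignalCriteria()
    exclusions = exclusions or ExclusionPolicy()
    cc = criteria.chi2_continuity_correction
    tables = build_all_tables(cases, drug, min_a=min_a)
    results: list[DispropResult] = []
    for pt, t in tables.items():
        r = compute_statistics(drug, pt, t, priors=priors, continuity_correction=cc)
        r = evaluate_signal(r, criteria)
        if pt in exclusions:
            r = replace(r, excluded=True)
        if vocab is not None:
            r = replace(r, soc=vocab[pt] if pt in vocab else "Unmapped")
        results.append(r)
    results.sort(key=lambda r: (-r.a, _key(r.pt)))
    return results


def aggregate_by_soc(results: Sequence[DispropResult],
                     vocab: VocabularyMap | None = None) -> list[SocSummary]:
    """Tally signal PTs per SOC, sorted by report sum descending.

    ``n_reports`` sums the a-cell over the SOC's signal PTs; ``n_signals``
    counts them.  PTs without a vocabulary entry fall into "Unmapped".
    Only SOCs with at least one signal appear.
    """
    reports: dict[str, int] = {}
    signals: dict[str, int] = {}
    for r in results:
        if not r.is_signal:
            continue
        soc = r.soc
        if soc is None:
            soc = vocab[r.pt] if (vocab is not None and r.pt in vocab) else "Unmapped"
        reports[soc] = reports.get(soc, 0) + r.a
        signals[soc] = signals.get(soc, 0) + 1
    out = [SocSummary(s, reports[s], signals[s]) for s in reports]
    out.sort(key=lambda s: (-s.n_reports, s.soc))
    return out


def subgroup(results: Sequence[DispropResult],
             pt_list: Iterable[str]) -> list[DispropResult]:
    """Filtered copy restricted to *pt_list* (case-insensitive), order kept."""
    keys = {_key(p) for p in pt_list}
    return [r for r in results if _key(r.pt) in keys]


def top_n(results: Sequence[DispropResult], key: str = "reports",
          n: int = 50) -> list[DispropResult]:
    """Rank results by report count or by signal strength (ROR).

    ``key="reports"`` sorts by a descending, ties by ROR descending;
    ``key="strength"`` sorts by ROR descending, ties by a descending;
    remaining ties break on PT ascending.  Undefined ROR sorts last.
    """
    def ror_of(r: DispropResult) -> float:
        return r.ror if r.ror is not None else float("-inf")

    if key == "reports":
        ranked = sorted(results, key=lambda r: (-r.a, -ror_of(r), _key(r.pt)))
    elif key == "strength":
        ranked = sorted(results, key=lambda r: (-ror_of(r), -r.a, _key(r.pt)))
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    return ranked[:n]


def annotate_label_status(results: Sequence[DispropResult],
                          labelled_pts: Iterable[str]) -> list[DispropResult]:
    """Flag each result as labelled (a known, documented ADR) or not."""
    keys = {_key(p) for p in labelled_pts}
    return [replace(r, labelled=_key(r.pt) in keys) for r in results]


RESULT_COLUMNS = [
    "pt", "reports", "b", "c", "d", "ror", "ror_ci_low", "ror_ci_high",
    "prr", "chi2", "ic", "ic_raw", "ic025",
    "ror_flag", "prr_flag", "bcpnn_flag", "signal", "excluded",
    "intensity", "labelled", "soc",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_results_csv(results: Sequence[DispropResult], path: str | Path) -> None:
    """Write the per-PT results table (one row per screened PT)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for r in results:
            w.writerow([_fmt(v) for v in (
                r.pt, r.a, r.b, r.c, r.d, r.ror, r.ror_ci_low, r.ror_ci_high,
                r.prr, r.chi2, r.ic_expected, r.ic_raw, r.ic_minus_2sd,
                r.ror_positive, r.prr_positive, r.bcpnn_positive,
                r.is_signal, r.excluded, r.intensity, r.labelled, r.soc,
            )])


def write_soc_csv(summaries: Sequence[SocSummary], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["soc", "n_reports", "n_signals"])
        for s in summaries:
            w.writerow([s.soc, s.n_reports, s.n_signals])


def screen_counts(results: Sequence[DispropResult]) -> dict[str, int]:
    """Stage counts of the screening flow, for the run log."""
    positives = sum(r.combined_signal for r in results)
    excluded_pos = sum(r.combined_signal and r.excluded for r in results)
    return {
        "tables_built": len(results),
        "triple_positive": positives,
        "excluded_positive": excluded_pos,
        "final_signals": positives - excluded_pos,
    }
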