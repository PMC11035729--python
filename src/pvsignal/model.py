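"""Model/results interface over the screening pipeline.

:class:`DisproportionalityAnalysis` is the entry point most users want: it
is constructed from case data (or straight from a report file) and its
:meth:`~DisproportionalityAnalysis.fit` evaluates the three
disproportionality methods for every observed preferred term, returning a
:class:`SignalScreenResults` that carries the per-PT estimates, their
uncertainty, the signal flags and the ranked report tables.

Example
-------
>>> model = DisproportionalityAnalysis.from_csv("reports.csv", drug="ticagrelor")
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
>>> res.to_frame().head()           # doctest: +SKIP
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import io as _io
from .disproportionality import BcpnnPriors, DispropResult, SignalCriteria
from . import screen as _screen
from .io import CaseView, ReportRecord, VocabularyMap
from .screen import ExclusionPolicy, SocSummary


class DisproportionalityAnalysis:
    """Disproportionality screen of one drug against a case universe.

    Parameters
    ----------
    cases
        Deduplicated case views (one per case id).
    drug
        Normalised generic name of the study drug; exposure means the drug
        is present with the primary-suspect role unless ``ps_only=False``.
    vocab
        Optional PT -> SOC vocabulary used for aggregation.
    exclusions
        Optional policy striking invalid PTs from the signal set.
    labelled_pts
        Optional set of PTs already documented in the product label.
    """

    def __init__(self, cases: Sequence[CaseView], drug: str,
                 vocab: VocabularyMap | None = None,
                 exclusions: ExclusionPolicy | None = None,
                 labelled_pts: Iterable[str] | None = None,
                 ps_only: bool = True, min_a: int = 1):
        self.cases = list(cases)
        self.drug = drug
        self.vocab = vocab
        self.exclusions = exclusions or ExclusionPolicy()
        self.labelled_pts = set(labelled_pts or ())
        self.ps_only = ps_only
        self.min_a = min_a

    @classmethod
    def from_reports(cls, reports: Sequence[ReportRecord], drug: str,
                     date_window: tuple[date | None, date | None] | None = None,
                     **kwargs) -> "DisproportionalityAnalysis":
        """Build from raw report records, deduplicating to cases first."""
        cases = _io.deduplicate_to_cases(reports)
        if date_window is not None:
            cases = _io.filter_date_window(cases, *date_window)
        return cls(cases, drug, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, drug: str, dialect: str = "flat_csv",
                 **kwargs) -> "DisproportionalityAnalysis":
        """Build straight from a report file in either supported dialect."""
        return cls.from_reports(_io.read_reports(path, dialect), drug, **kwargs)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_exposed(self) -> int:
        role = "PS" if self.ps_only else None
        return sum(c.has_drug(self.drug, role=role) for c in self.cases)

    def fit(self, criteria: SignalCriteria | None = None,
            priors: BcpnnPriors | None = None) -> "SignalScreenResults":
        """Run the screen and evaluate the triple-positive signal rule."""
        criteria = criteria or SignalCriteria()
        results = _screen.run_screen(
            self.cases, self.drug, criteria=criteria,
            exclusions=self.exclusions, vocab=self.vocab,
            priors=priors, min_a=self.min_a,
        )
        if self.labelled_pts:
            results = _screen.annotate_label_status(results, self.labelled_pts)
        return SignalScreenResults(self, results, criteria)


class SignalScreenResults:
    """Per-PT disproportionality estimates and signal decisions."""

    def __init__(self, model: DisproportionalityAnalysis,
                 results: list[DispropResult], criteria: SignalCriteria):
        self.model = model
        self.results = results
        self.criteria = criteria
        self.run_log = {
            "drug": model.drug,
            "n_cases": model.n_cases,
            "n_exposed": model.n_exposed,
            **_screen.screen_counts(results),
        }

    # -- accessors ---------------------------------------------------------

    @property
    def signals(self) -> list[DispropResult]:
        return [r for r in self.results if r.is_signal]

    def to_frame(self) -> pd.DataFrame:
        """All screened PTs as a DataFrame (one row per PT)."""
        rows = []
        for r in self.results:
            rows.append({
                "pt": r.pt, "reports": r.a, "b": r.b, "c": r.c, "d": r.d,
                "ror": r.ror, "ror_ci_low": r.ror_ci_low,
                "ror_ci_high": r.ror_ci_high, "prr": r.prr, "chi2": r.chi2,
                "ic": r.ic_expected, "ic_raw": r.ic_raw,
                "ic025": r.ic_minus_2sd,
                "ror_flag": r.ror_positive, "prr_flag": r.prr_positive,
                "bcpnn_flag": r.bcpnn_positive, "signal": r.is_signal,
                "excluded": r.excluded, "intensity": r.intensity,
                "labelled": r.labelled, "soc": r.soc,
            })
        return pd.DataFrame(rows)

    def soc_summary(self) -> list[SocSummary]:
        return _screen.aggregate_by_soc(self.results, self.model.vocab)

    def top_n(self, key: str = "reports", n: int = 50,
              signals_only: bool = True) -> list[DispropResult]:
        pool = self.signals if signals_only else self.results
        return _screen.top_n(pool, key=key, n=n)

    def subgroup(self, pt_list: Iterable[str]) -> list[DispropResult]:
        return _screen.subgroup(self.results, pt_list)

    # -- presentation ------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Human-readable run overview with the leading signals."""
        log = self.run_log
        lines = [
            "Disproportionality screen",
            "=" * 25,
            f"drug:                 {log['drug']}",
            f"cases (universe N):   {log['n_cases']:,}",
            f"drug-exposed cases:   {log['n_exposed']:,}",
            f"PT tables built:      {log['tables_built']:,}",
            f"triple-positive PTs:  {log['triple_positive']:,}",
            f"excluded positives:   {log['excluded_positive']:,}",
            f"final signals:        {log['final_signals']:,}",
            "",
            f"{'PT':<32}{'reports':>8}{'ROR':>9}{'95% CI':>18}"
            f"{'PRR':>8}{'chi2':>11}{'IC':>7}{'IC025':>8}",
        ]
        def num(x, width, prec=2):
            return f"{x:>{width}.{prec}f}" if x is not None else " " * width

        for r in self.top_n(key="reports", n=top):
            ci = (f"({r.ror_ci_low:.2f}-{r.ror_ci_high:.2f})"
                  if r.ror_ci_low is not None else "")
            lines.append(
                f"{r.pt:<32}{r.a:>8}" + num(r.ror, 9) + f"{ci:>18}"
                + num(r.prr, 8) + num(r.chi2, 11) + num(r.ic_raw, 7)
                + num(r.ic_minus_2sd, 8)
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path, top: int = 50) -> None:
        """Write results.csv, soc_summary.csv, ranked tables and run_log.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _screen.write_results_csv(self.results, outdir / "results.csv")
        _screen.write_soc_csv(self.soc_summary(), outdir / "soc_summary.csv")
        _screen.write_results_csv(self.top_n("reports", top),
                                  outdir / "top_by_reports.csv")
        _screen.write_results_csv(self.top_n("strength", top),
                                  outdir / "top_by_strength.csv")
        with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(self.run_log, fh, indent=2)

    def plot_signals(self, ax=None):
        """Scatter of IC025 against report count, signals highlighted.

        Requires matplotlib (optional dependency).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        xs = [r.a for r in self.results if r.ic_minus_2sd is not None]
        ys = [r.ic_minus_2sd for r in self.results if r.ic_minus_2sd is not None]
        sig = [r.is_signal for r in self.results if r.ic_minus_2sd is not None]
        colors = ["tab:red" if s else "tab:gray" for s in sig]
        ax.scatter(xs, ys, c=colors, s=12, alpha=0.7)
        ax.axhline(self.criteria.ic025_gt, ls="--", lw=0.8, c="k")
        ax.set_xscale("log")
        ax.set_xlabel("reports with drug and event (a)")
        ax.set_ylabel("IC025 (bits)")
        ax.set_title(f"{self.model.drug}: {self.run_log['final_signals']} signals")
        return ax
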