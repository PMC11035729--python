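"""Case-level 2x2 contingency tables for drug-event pairs.

The table orientation is fixed with rows = drug exposure and columns =
event, so that ROR = (a/c)/(b/d) and PRR = [a/(a+b)]/[c/(c+d)]:

================  ==========  =============
 .                event       no event
================  ==========  =============
drug (PS)         a           b
all other cases   c           d
================  ==========  =============

Counting unit is the *case*: each deduplicated case contributes exactly one
to exactly one cell, so the drug margin a+b is the number of drug-exposed
cases and is constant across events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import CaseView, _key, normalize_term


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one (drug, event) pair over the whole case universe."""

    a: int  # drug and event
    b: int  # drug, not event
    c: int  # event, not drug
    d: int  # neither

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        """Margin a+b: number of drug-exposed cases."""
        return self.a + self.b

    @property
    def event_total(self) -> int:
        """Margin a+c: number of cases with the event."""
        return self.a + self.c

    # margin probabilities of the information-component formulation
    @property
    def px(self) -> float:
        return self.drug_total / self.n

    @property
    def py(self) -> float:
        return self.event_total / self.n

    @property
    def pxy(self) -> float:
        return self.a / self.n

    @property
    def degenerate(self) -> bool:
        return self.n == 0


def _exposed(case: CaseView, drug: str, ps_only: bool) -> bool:
    return case.has_drug(drug, role="PS" if ps_only else None)


def build_table(cases: Sequence[CaseView], drug: str, event: str,
                ps_only: bool = True) -> ContingencyTable:
    """Count the 2x2 table for one (drug, event) pair.

    Exposure means the drug is present with the primary-suspect role
    (``ps_only=False`` relaxes to any role).  An empty case list yields the
    all-zero table, which is valid but flagged degenerate downstream.
    """
    ek = _key(event)
    a = b = c = d = 0
    for case in cases:
        has_drug = _exposed(case, drug, ps_only)
        has_event = any(_key(pt) == ek for pt in case.pts)
        if has_drug:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def build_all_tables(cases: Sequence[CaseView], drug: str, min_a: int = 1,
                     ps_only: bool = True) -> dict[str, ContingencyTable]:
    """One table per PT observed among drug-exposed cases with a >= min_a.

    All returned tables share the same N (the case-universe size) and the
    same drug margin a+b.  A single pass over the cases counts, for every
    PT, the exposed-with-event cell a and the overall event margin a+c;
    b and d follow from the margins.  Keys are PTs in first-seen spelling,
    sorted; lookups elsewhere normalise case.
    """
    n = len(cases)
    exposed_total = 0
    a_counts: dict[str, int] = {}
    event_totals: dict[str, int] = {}
    display: dict[str, str] = {}

    for case in cases:
        has_drug = _exposed(case, drug, ps_only)
        if has_drug:
            exposed_total += 1
        seen: set[str] = set()
        for pt in case.pts:
            k = _key(pt)
            if k in seen:
                continue
            seen.add(k)
            display.setdefault(k, normalize_term(pt))
            event_totals[k] = event_totals.get(k, 0) + 1
            if has_drug:
                a_counts[k] = a_counts.get(k, 0) + 1

    out: dict[str, ContingencyTable] = {}
    for k in sorted(a_counts, key=lambda k: display[k]):
        a = a_counts[k]
        if a < min_a:
            continue
        b = exposed_total - a
        c = event_totals[k] - a
        d = n - a - b - c
        out[display[k]] = ContingencyTable(a, b, c, d)
    return out


def tables_to_rows(tables: Mapping[str, ContingencyTable]) -> Iterable[tuple]:
    """Yield ``(pt, a, b, c, d)`` rows for CSV export."""
    for pt, t in tables.items():
        yield (pt, t.a, t.b, t.c, t.d)
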