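"""Invert printed per-PT statistics back to integer 2x2 tables.

Published disproportionality tables typically print, per preferred term,
the report count a, the ROR and the PRR — but not the full 2x2 table.  When
the two margins are also printed (the drug-exposed case total a+b and the
database-wide case total N), the remaining cell c is recoverable: PRR
determines c up to rounding via

    c = a·(N − (a+b)) / ((a+b)·PRR)

and an integer search around that seed, scored against both the printed
ROR and PRR, pins it down.  The recovered table then lets every other
statistic (chi-squared, E(IC), IC025, CI bounds) be recomputed and audited
against the publication at printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .contingency import ContingencyTable
from .disproportionality import prr_with_chi2, ror_with_ci

#: Margins of the ticagrelor study universe: primary-suspect case total and
#: database-wide case total over 2010-10-01..2023-03-31.
TICAGRELOR_DRUG_TOTAL = 12_909
TICAGRELOR_N_TOTAL = 9_699_440


class InconsistencyError(ValueError):
    """No integer table reproduces the printed statistics at 2 decimals."""


@dataclass(frozen=True)
class PrintedRow:
    """One published table row: count plus rounded ROR and PRR."""

    pt: str
    a: int
    ror_printed: float
    prr_printed: float
    drug_total: int = TICAGRELOR_DRUG_TOTAL
    n_total: int = TICAGRELOR_N_TOTAL

    def __post_init__(self):
        if not (0 < self.a <= self.drug_total <= self.n_total):
            raise ValueError("need 0 < a <= drug_total <= n_total")
        if self.ror_printed <= 0 or self.prr_printed <= 0:
            raise ValueError("printed ROR and PRR must be positive")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at *decimals* places (print convention)."""
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def _score(t: ContingencyTable, row: PrintedRow) -> float:
    ror, _, _ = ror_with_ci(t)
    prr, _ = prr_with_chi2(t, continuity_correction=False)
    if ror is None or prr is None:
        return math.inf
    return (((ror - row.ror_printed) / row.ror_printed) ** 2
            + ((prr - row.prr_printed) / row.prr_printed) ** 2)


def reconstruct_table(row: PrintedRow, window: float = 0.02,
                      decimals: int = 2) -> ContingencyTable:
    """Recover the integer 2x2 table behind a printed row.

    b follows from the drug margin; c is seeded by inverting the PRR and
    refined by integer search over a ±``window`` relative band, minimising
    the squared relative deviation of the recomputed (ROR, PRR) from the
    printed pair.  The winning table must reproduce both printed values
    after half-up rounding at ``decimals`` places, else an
    :class:`InconsistencyError` reports the residuals.

    Printed values carrying fewer significant decimals (e.g. "13.5") are
    accepted by comparing at the precision actually printed: pass the
    value as printed and, if needed, a smaller ``decimals``.
    """
    b = row.drug_total - row.a
    comparator = row.n_total - row.drug_total
    c0 = row.a * comparator / (row.drug_total * row.prr_printed)
    lo = max(1, math.floor(c0 * (1 - window)) - 1)
    hi = min(comparator, math.ceil(c0 * (1 + window)) + 1)
    best_c, best_score = None, math.inf
    for c in range(lo, hi + 1):
        d = comparator - c
        if d < 0:
            break
        t = ContingencyTable(row.a, b, c, d)
        s = _score(t, row)
        if s < best_score:
            best_c, best_score = c, s
    if best_c is None:
        raise InconsistencyError(f"{row.pt}: no feasible c in search window")
    t = ContingencyTable(row.a, b, best_c, comparator - best_c)
    ror, _, _ = ror_with_ci(t)
    prr, _ = prr_with_chi2(t, continuity_correction=False)
    ror_r = round_half_up(ror, decimals)
    prr_r = round_half_up(prr, decimals)
    if not (math.isclose(ror_r, round_half_up(row.ror_printed, decimals))
            and math.isclose(prr_r, round_half_up(row.prr_printed, decimals))):
        raise InconsistencyError(
            f"{row.pt}: best table (c={best_c}) gives ROR={ror:.4f} "
            f"PRR={prr:.4f}, printed {row.ror_printed}/{row.prr_printed}"
        )
    return t
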