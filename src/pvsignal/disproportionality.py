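"""Disproportionality statistics: ROR, PRR with chi-squared, and BCPNN.

Three frequentist/Bayesian measures of reporting disproportionality are
computed from a case-level 2x2 table (see :mod:`pvsignal.contingency` for
the orientation):

* **ROR** — reporting odds ratio ``ad/(bc)`` with a Wald 95% CI on the log
  scale, ``exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` paired
  with the 2x2 chi-squared statistic; the Yates continuity correction
  (subtract N/2 from |ad−bc| before squaring, floored at 0) is applied by
  default.
* **BCPNN information component** — the posterior mean E(IC) and variance
  V(IC) of the log2 observed/expected joint reporting probability under the
  Bayesian confidence propagation neural network priors of Bate et al.
  (1998), and the normal-approximation lower bound IC025 = E(IC) − 2·√V(IC).

A drug-event pair is a *signal* when all three methods are positive under
their conventional thresholds (a>3 and: ROR CI lower bound >1; PRR>2 with
chi-squared>4; IC025>0).  Statistics whose defining ratios involve a zero
cell are undefined and make the corresponding method negative; an optional
Haldane 0.5 continuity correction can be opted into for exploratory work,
flagging the result as corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .contingency import ContingencyTable

_LN2_SQ = math.log(2.0) ** 2
_Z95 = 1.96

INTENSITY_LEVELS = ("none", "+", "++", "+++")


@dataclass(frozen=True)
class BcpnnPriors:
    """Dirichlet hyperparameters of the BCPNN posterior.

    Defaults are the standard choice α1=β1=1, α=β=2, γ11=1; the joint prior
    weight γ is derived from the table margins as
    γ11·(N+α)(N+β)/((a+b+α1)(a+c+β1)), which centres the prior IC at 0.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ValueError("BCPNN priors must be strictly positive")

    def gamma(self, t: ContingencyTable) -> float:
        n = t.n
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((t.drug_total + self.alpha1) * (t.event_total + self.beta1)))


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds for the three methods and the combined signal rule.

    All inequalities are strict.  ``min_a`` is a strict lower bound
    (default a > 3).  ``intensity_thresholds`` are ascending cut-points on
    the E(IC) scale partitioning combined signals into +, ++, +++.
    """

    min_a: int = 3
    ror_ci_low_gt: float = 1.0
    prr_gt: float = 2.0
    chi2_gt: float = 4.0
    ic025_gt: float = 0.0
    chi2_continuity_correction: bool = True
    intensity_thresholds: tuple[float, float] = (1.5, 3.0)

    def __post_init__(self):
        lo, hi = self.intensity_thresholds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError("intensity_thresholds must be finite and ascending")


@dataclass
class DispropResult:
    """All statistics and signal flags for one (drug, PT) pair."""

    drug: str
    pt: str
    a: int
    b: int = 0
    c: int = 0
    d: int = 0
    ror: float | None = None
    ror_ci_low: float | None = None
    ror_ci_high: float | None = None
    prr: float | None = None
    chi2: float | None = None
    ic_expected: float | None = None
    ic_variance: float | None = None
    ic_minus_2sd: float | None = None
    ic_raw: float | None = None
    corrected: bool = False
    ror_positive: bool = False
    prr_positive: bool = False
    bcpnn_positive: bool = False
    combined_signal: bool = False
    intensity: str = "none"
    excluded: bool = False
    labelled: bool | None = None
    soc: str | None = None

    @property
    def is_signal(self) -> bool:
        """Triple-positive and not struck by the exclusion list."""
        return self.combined_signal and not self.excluded


def ror_with_ci(t: ContingencyTable, haldane: bool = False
                ) -> tuple[float | None, float | None, float | None]:
    """Reporting odds ratio with its Wald 95% confidence interval.

    Undefined (``None`` triple) when any cell is zero, unless ``haldane``
    adds 0.5 to every cell (callers must then mark the result corrected).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        return None, None, None
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - _Z95 * se), math.exp(log_ror + _Z95 * se)


def prr_with_chi2(t: ContingencyTable, continuity_correction: bool = True,
                  haldane: bool = False) -> tuple[float | None, float | None]:
    """Proportional reporting ratio and the 2x2 chi-squared statistic.

    PRR is undefined when the drug margin is empty or no comparator case
    has the event; chi-squared is undefined when any margin is zero.  With
    the Yates correction the |ad−bc| − N/2 term floors at zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d

    prr: float | None
    if (a + b) <= 0 or c <= 0:
        prr = None
    else:
        prr = (a / (a + b)) / (c / (c + d))

    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        chi2 = None
    else:
        diff = abs(a * d - b * c)
        if continuity_correction:
            diff = max(diff - n / 2, 0.0)
        chi2 = diff * diff * n / denom
    return prr, chi2


def bcpnn(t: ContingencyTable, priors: BcpnnPriors | None = None
          ) -> tuple[float, float, float]:
    """BCPNN posterior moments of the information component.

    Returns ``(E(IC), V(IC), IC025)`` where IC025 = E(IC) − 2·√V(IC).  The
    priors regularise the zero-a case; an empty table (N=0) is an error.
    """
    if priors is None:
        priors = BcpnnPriors()
    n = t.n
    if n <= 0:
        raise ValueError("BCPNN undefined on an empty table (N=0)")
    a = t.a
    row = t.drug_total
    col = t.event_total
    p = priors
    g = p.gamma(t)

    e_ic = math.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
        / ((n + g) * (row + p.alpha1) * (col + p.beta1))
    )
    v_ic = (
        (n - a + g - p.gamma11) / ((a + p.gamma11) * (1 + n + g))
        + (n - row + p.alpha - p.alpha1) / ((row + p.alpha1) * (1 + n + p.alpha))
        + (n - col + p.beta - p.beta1) / ((col + p.beta1) * (1 + n + p.beta))
    ) / _LN2_SQ
    return e_ic, v_ic, e_ic - 2.0 * math.sqrt(v_ic)


def raw_ic(t: ContingencyTable) -> float | None:
    """Maximum-likelihood information component log2(aN/((a+b)(a+c)))."""
    if t.a <= 0 or t.drug_total <= 0 or t.event_total <= 0 or t.n <= 0:
        return None
    return math.log2(t.a * t.n / (t.drug_total * t.event_total))


def compute_statistics(drug: str, pt: str, t: ContingencyTable,
                       priors: BcpnnPriors | None = None,
                       continuity_correction: bool = True,
                       haldane: bool = False) -> DispropResult:
    """Evaluate all three methods on one table (no signal flags yet)."""
    ror, lo, hi = ror_with_ci(t, haldane=haldane)
    prr, chi2 = prr_with_chi2(t, continuity_correction=continuity_correction,
                              haldane=haldane)
    if t.n > 0:
        e_ic, v_ic, ic025 = bcpnn(t, priors)
    else:
        e_ic = v_ic = ic025 = None
    return DispropResult(
        drug=drug, pt=pt, a=t.a, b=t.b, c=t.c, d=t.d,
        ror=ror, ror_ci_low=lo, ror_ci_high=hi,
        prr=prr, chi2=chi2,
        ic_expected=e_ic, ic_variance=v_ic, ic_minus_2sd=ic025,
        ic_raw=raw_ic(t), corrected=haldane,
    )


def evaluate_signal(r: DispropResult, crit: SignalCriteria | None = None
                    ) -> DispropResult:
    """Fill per-method flags, the combined signal and the intensity grade.

    An undefined statistic makes its method negative.  The combined signal
    is the conjunction of the three method flags; intensity is graded on
    E(IC) against the criteria cut-points only for combined signals.
    """
    if crit is None:
        crit = SignalCriteria()
    big_enough = r.a > crit.min_a
    ror_pos = (big_enough and r.ror_ci_low is not None
               and r.ror_ci_low > crit.ror_ci_low_gt)
    prr_pos = (big_enough and r.prr is not None and r.chi2 is not None
               and r.prr > crit.prr_gt and r.chi2 > crit.chi2_gt)
    bcpnn_pos = (big_enough and r.ic_minus_2sd is not None
                 and r.ic_minus_2sd > crit.ic025_gt)
    combined = ror_pos and prr_pos and bcpnn_pos
    intensity = "none"
    if combined and r.ic_expected is not None:
        lo, hi = crit.intensity_thresholds
        if r.ic_expected > hi:
            intensity = "+++"
        elif r.ic_expected > lo:
            intensity = "++"
        else:
            intensity = "+"
    return replace(r, ror_positive=ror_pos, prr_positive=prr_pos,
                   bcpnn_positive=bcpnn_pos, combined_signal=combined,
                   intensity=intensity)
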