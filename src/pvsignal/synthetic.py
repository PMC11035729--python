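"""Synthetic spontaneous-report generator with known ground truth.

Emulates the case/report structure of a spontaneous adverse-event database
so every pipeline stage can be exercised, and its operating characteristics
measured, without any download.  The generative model:

* each case independently realises drug exposures from per-drug marginal
  probabilities; one exposed drug may become the primary suspect (PS) via a
  per-drug PS probability, the rest are concomitant;
* each event (preferred term) is Bernoulli with probability
  ``min(1, λ_e · Π_{d exposed} ρ_{d,e})`` — λ is the per-case baseline
  reporting rate and ρ a relative reporting rate, so planted pairs with
  ρ>1 are enriched among exposed cases and ρ approximates the PRR at low
  baselines;
* cases realising no event (or no exposed drug — a spontaneous report
  always names a drug) are redrawn, with redraw counts logged in the
  manifest;
* a configurable fraction of cases emits additional report versions that
  repeat the full case content, exercising case-level deduplication;
* demographics (sex, age band, country, year) are sampled from categorical
  distributions shaped like the published summary of the ticagrelor FAERS
  cohort.

Everything is reproducible from the seed, and a :class:`TruthManifest`
records expected and realised 2x2 counts per (drug, PT) pair so pipeline
output can be compared against ground truth exactly.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contingency import build_all_tables
from .disproportionality import (
    BcpnnPriors,
    SignalCriteria,
    compute_statistics,
    evaluate_signal,
)
from .io import DrugEntry, ReportRecord, deduplicate_to_cases


@dataclass(frozen=True)
class DrugSpec:
    """One drug: marginal exposure probability and P(PS | exposed)."""

    name: str
    exposure_prob: float
    ps_prob: float = 1.0

    def __post_init__(self):
        if not (0 <= self.exposure_prob <= 1 and 0 <= self.ps_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EventSpec:
    """One preferred term with its SOC and baseline per-case rate."""

    pt: str
    soc: str
    baseline_rate: float

    def __post_init__(self):
        if not 0 <= self.baseline_rate <= 1:
            raise ValueError("baseline_rate must lie in [0, 1]")


# demographic category weights shaped like the published cohort summary
_DEFAULT_SEX = {"male": 0.575, "female": 0.334, "unknown": 0.091}
_DEFAULT_AGE_BANDS = {
    "<18": 0.02, "18-44": 0.12, "45-64": 0.25, "65-84": 0.26,
    ">=85": 0.05, "unknown": 0.30,
}
_AGE_RANGES = {"<18": (1, 17), "18-44": (18, 44), "45-64": (45, 64),
               "65-84": (65, 84), ">=85": (85, 99)}
_DEFAULT_COUNTRY = {"US": 0.62, "CA": 0.06, "GB": 0.05, "JP": 0.05,
                    "other": 0.22}
_DEFAULT_YEAR = {str(y): w for y, w in zip(
    range(2011, 2024),
    [0.02, 0.03, 0.05, 0.08, 0.12, 0.25, 0.12, 0.09, 0.07, 0.06, 0.05,
     0.04, 0.02],
)}


@dataclass
class SyntheticConfig:
    """Full parameterisation of the generator (see module docstring)."""

    n_cases: int
    drugs: Sequence[DrugSpec]
    events: Sequence[EventSpec]
    rr: Mapping[tuple[str, str], float] = field(default_factory=dict)
    duplicate_report_rate: float = 0.2
    max_versions: int = 3
    sex_dist: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SEX))
    age_band_dist: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_BANDS))
    country_dist: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTRY))
    year_dist: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_YEAR))
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if not 0 <= self.duplicate_report_rate <= 1:
            raise ValueError("duplicate_report_rate must lie in [0, 1]")
        if self.max_versions < 1:
            raise ValueError("max_versions must be >= 1")
        names = {d.name for d in self.drugs}
        pts = {e.pt for e in self.events}
        for (d, e), rho in self.rr.items():
            if d not in names or e not in pts:
                raise ValueError(f"rr entry ({d!r}, {e!r}) not in config")
            if rho < 0:
                raise ValueError("relative reporting rates must be >= 0")

    def rho(self, drug: str, pt: str) -> float:
        return self.rr.get((drug, pt), 1.0)

    @property
    def planted(self) -> set[tuple[str, str]]:
        """Pairs with a planted association (ρ > 1)."""
        return {k for k, v in self.rr.items() if v > 1}

    @classmethod
    def example(cls, n_cases: int = 20_000, n_null_events: int = 30,
                n_planted: int = 5, rho: float = 10.0,
                planted_rate: float = 0.004, seed: int = 0
                ) -> "SyntheticConfig":
        """A two-drug study-like configuration with planted signals.

        The study drug is exposed in 5% of cases and is the primary suspect
        for 90% of its exposures; a widely-used comparator medication
        covers 90% of cases.  ``n_planted`` events get relative reporting
        rate ``rho`` under the study drug (default 10, giving expected
        a ≈ 36 per planted pair at 20,000 cases); the null events span
        baseline rates 0.002-0.03 across four organ classes.
        """
        drugs = [DrugSpec("ticagrelor", 0.05, 0.9),
                 DrugSpec("comedication", 0.9, 0.05)]
        socs = ["Cardiac disorders",
                "Respiratory, thoracic and mediastinal disorders",
                "Gastrointestinal disorders",
                "Nervous system disorders"]
        rates = np.geomspace(0.002, 0.03, n_null_events)
        events = [EventSpec(f"Null event {i:02d}", socs[i % len(socs)], float(r))
                  for i, r in enumerate(rates)]
        events += [EventSpec(f"Planted event {i:02d}", socs[i % len(socs)],
                             planted_rate) for i in range(n_planted)]
        rr = {("ticagrelor", f"Planted event {i:02d}"): rho
              for i in range(n_planted)}
        return cls(n_cases=n_cases, drugs=drugs, events=events, rr=rr,
                   seed=seed)


@dataclass
class TruthManifest:
    """Ground truth recorded alongside a generated dataset."""

    n_cases: int
    n_reports: int
    expected_a: dict[str, float]        # "drug|pt" -> expected a
    realized: dict[str, tuple[int, int, int, int]]  # "drug|pt" -> (a,b,c,d)
    planted: list[tuple[str, str]]
    ps_case_counts: dict[str, int]      # drug -> cases with drug as PS
    report_versions: list[int]          # per-case version counts
    n_event_redraws: int = 0
    n_drug_redraws: int = 0

    @staticmethod
    def key(drug: str, pt: str) -> str:
        return f"{drug}|{pt}"

    def realized_table(self, drug: str, pt: str) -> tuple[int, int, int, int]:
        return tuple(self.realized[self.key(drug, pt)])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["planted"] = [tuple(p) for p in d["planted"]]
        d["realized"] = {k: tuple(v) for k, v in d["realized"].items()}
        return cls(**d)


def _sample_categorical(rng: np.random.Generator, dist: Mapping[str, float],
                        n: int) -> np.ndarray:
    cats = list(dist)
    w = np.asarray([dist[c] for c in cats], dtype=float)
    w = w / w.sum()
    return rng.choice(np.asarray(cats, dtype=object), size=n, p=w)


def _draw_case_content(rng: np.random.Generator, cfg: SyntheticConfig,
                       n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Sample exposure, PS designation and events for *n* cases.

    Returns (exposed, ps, events, n_drug_redraws, n_event_redraws) where
    ``exposed`` and ``ps`` are (n, n_drugs) booleans (ps has at most one
    True per row) and ``events`` is (n, n_events) boolean.
    """
    n_drugs = len(cfg.drugs)
    n_events = len(cfg.events)
    exp_p = np.array([d.exposure_prob for d in cfg.drugs])
    ps_p = np.array([d.ps_prob for d in cfg.drugs])
    lam = np.array([e.baseline_rate for e in cfg.events])
    # per-(drug,event) multiplier matrix
    mult = np.ones((n_drugs, n_events))
    for (dn, pt), rho in cfg.rr.items():
        di = next(i for i, d in enumerate(cfg.drugs) if d.name == dn)
        ei = next(i for i, e in enumerate(cfg.events) if e.pt == pt)
        mult[di, ei] = rho

    exposed = np.zeros((n, n_drugs), dtype=bool)
    events = np.zeros((n, n_events), dtype=bool)
    drug_redraws = 0
    event_redraws = 0

    todo = np.arange(n)
    while todo.size:  # redraw cases with no exposed drug
        m = todo.size
        draw = rng.random((m, n_drugs)) < exp_p
        exposed[todo] = draw
        ok = draw.any(axis=1)
        todo = todo[~ok]
        drug_redraws += int((~ok).sum())
        if n_drugs == 0 or exp_p.max() == 0:
            raise ValueError("no drug can be exposed; config degenerate")

    todo = np.arange(n)
    while todo.size:  # redraw cases with no event
        m = todo.size
        # event probability given this row's exposures
        logm = np.log(np.where(mult > 0, mult, 1.0))
        zero_mask = mult == 0
        p = lam * np.exp(exposed[todo] @ logm)
        if zero_mask.any():
            killed = exposed[todo] @ zero_mask.astype(float) > 0
            p = np.where(killed, 0.0, p)
        p = np.minimum(p, 1.0)
        draw = rng.random((m, n_events)) < p
        events[todo] = draw
        ok = draw.any(axis=1)
        todo = todo[~ok]
        event_redraws += int((~ok).sum())
        if lam.max() == 0:
            raise ValueError("all baseline rates are zero; config degenerate")

    # primary-suspect designation: among exposed drugs passing their PS
    # coin, the one with the highest random priority wins
    coin = (rng.random((n, n_drugs)) < ps_p) & exposed
    prio = rng.random((n, n_drugs))
    prio[~coin] = -1.0
    ps = np.zeros_like(exposed)
    has_ps = coin.any(axis=1)
    winners = prio.argmax(axis=1)
    ps[np.arange(n)[has_ps], winners[has_ps]] = True
    return exposed, ps, events, drug_redraws, event_redraws


def _ps_win_prob(ps_probs: list[float], idx: int) -> float:
    """P(drug *idx* becomes PS) given this set of exposed drugs.

    Each exposed drug passes an independent coin with its PS probability;
    the winner is uniform among passers.
    """
    others = [p for j, p in enumerate(ps_probs) if j != idx]
    total = 0.0
    for bits in itertools.product((0, 1), repeat=len(others)):
        w = 1.0
        for passed, p in zip(bits, others):
            w *= p if passed else 1 - p
        total += w / (1 + sum(bits))
    return ps_probs[idx] * total


def _expected_a(cfg: SyntheticConfig) -> dict[str, float]:
    """Exact E[a] per (drug, pt) under the generative model.

    Enumerates exposure patterns (conditioned on at least one exposed drug)
    and applies the at-least-one-event conditioning P(e | any) = p_e/p_any,
    which the redraw rule induces.  Falls back to the unconditional
    approximation beyond 12 drugs, where enumeration is too wide.
    """
    drugs, events = list(cfg.drugs), list(cfg.events)
    out = {TruthManifest.key(d.name, e.pt): 0.0
           for d in drugs for e in events}
    if len(drugs) > 12:
        for d in drugs:
            for e in events:
                p_event = min(1.0, e.baseline_rate * cfg.rho(d.name, e.pt))
                out[TruthManifest.key(d.name, e.pt)] = (
                    cfg.n_cases * d.exposure_prob * d.ps_prob * p_event)
        return out

    p_some_drug = 1.0 - math.prod(1 - d.exposure_prob for d in drugs)
    if p_some_drug == 0:
        return out
    for bits in itertools.product((0, 1), repeat=len(drugs)):
        if not any(bits):
            continue
        p_pattern = math.prod(
            d.exposure_prob if on else 1 - d.exposure_prob
            for on, d in zip(bits, drugs)) / p_some_drug
        exposed = [i for i, on in enumerate(bits) if on]
        p_events = [
            min(1.0, e.baseline_rate * math.prod(
                cfg.rho(drugs[i].name, e.pt) for i in exposed))
            for e in events
        ]
        p_any = 1.0 - math.prod(1 - p for p in p_events)
        if p_any == 0:
            continue
        ps_probs = [drugs[i].ps_prob for i in exposed]
        for k, i in enumerate(exposed):
            p_win = _ps_win_prob(ps_probs, k)
            for e, p_e in zip(events, p_events):
                out[TruthManifest.key(drugs[i].name, e.pt)] += (
                    cfg.n_cases * p_pattern * p_win * p_e / p_any)
    return out


def generate_cases(config: SyntheticConfig, seed: int | None = None
                   ) -> tuple[list[ReportRecord], TruthManifest]:
    """Generate report records and the matching ground-truth manifest.

    Duplicate report versions repeat the full case content, so case-level
    deduplication must recover exactly ``n_cases`` cases with unchanged
    drug-event content.  Fully reproducible from the seed (``config.seed``
    unless overridden).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_cases
    if n == 0:
        manifest = TruthManifest(0, 0, _expected_a(config), {},
                                 sorted(config.planted),
                                 {d.name: 0 for d in config.drugs}, [])
        return [], manifest

    exposed, ps, events, ndr, ner = _draw_case_content(rng, config, n)

    # realized 2x2 counts per (drug, pt) with PS-role exposure
    realized: dict[str, tuple[int, int, int, int]] = {}
    for di, d in enumerate(config.drugs):
        ps_col = ps[:, di]
        n_ps = int(ps_col.sum())
        for ei, e in enumerate(config.events):
            a = int((ps_col & events[:, ei]).sum())
            ev_total = int(events[:, ei].sum())
            b = n_ps - a
            c = ev_total - a
            realized[TruthManifest.key(d.name, e.pt)] = (a, b, c, n - a - b - c)

    # demographics and report versioning
    sex = _sample_categorical(rng, config.sex_dist, n)
    bands = _sample_categorical(rng, config.age_band_dist, n)
    country = _sample_categorical(rng, config.country_dist, n)
    years = _sample_categorical(rng, config.year_dist, n).astype(int)
    day_offsets = rng.integers(0, 365, size=n)
    ages = np.full(n, np.nan)
    for band, (lo, hi) in _AGE_RANGES.items():
        m = bands == band
        ages[m] = rng.integers(lo, hi + 1, size=int(m.sum()))

    dup = rng.random(n) < config.duplicate_report_rate
    extra = rng.geometric(0.5, size=n)
    versions = np.where(dup, 1 + np.minimum(extra, config.max_versions - 1), 1)

    reports: list[ReportRecord] = []
    width = len(str(n))
    for i in range(n):
        case_id = f"C{i:0{width}d}"
        drugs = []
        for di, d in enumerate(config.drugs):
            if ps[i, di]:
                drugs.append(DrugEntry(d.name, "PS"))
            elif exposed[i, di]:
                drugs.append(DrugEntry(d.name, "C"))
        pts = {config.events[ei].pt for ei in np.flatnonzero(events[i])}
        base_date = date(int(years[i]), 1, 1) + timedelta(days=int(day_offsets[i]))
        for v in range(1, int(versions[i]) + 1):
            reports.append(ReportRecord(
                case_id=case_id,
                report_id=f"{case_id}-{v}",
                version_seq=v,
                receipt_date=base_date + timedelta(days=30 * (v - 1)),
                sex=str(sex[i]),
                age_years=None if np.isnan(ages[i]) else float(ages[i]),
                country=str(country[i]),
                drugs=drugs,
                events=set(pts),
            ))

    manifest = TruthManifest(
        n_cases=n,
        n_reports=len(reports),
        expected_a=_expected_a(config),
        realized=realized,
        planted=sorted(config.planted),
        ps_case_counts={d.name: int(ps[:, di].sum())
                        for di, d in enumerate(config.drugs)},
        report_versions=[int(v) for v in versions],
        n_event_redraws=ner,
        n_drug_redraws=ndr,
    )
    return reports, manifest


def generate_vocabulary(config: SyntheticConfig) -> dict[str, str]:
    """PT -> SOC mapping covering every event the generator can emit."""
    return {e.pt: e.soc for e in config.events}


def operating_characteristics(config: SyntheticConfig,
                              criteria: SignalCriteria | None = None,
                              n_reps: int = 100, seed: int = 0,
                              drug: str | None = None,
                              priors: BcpnnPriors | None = None
                              ) -> pd.DataFrame:
    """False-positive rate and sensitivity of each method over replicates.

    For each replicate a fresh dataset is generated, deduplicated and
    screened through the full pipeline for *drug* (default: the first drug
    with a planted association).  Null pairs are that drug's events with
    ρ = 1, planted pairs those with ρ > 1.  Returns a DataFrame indexed by
    method (``ror``, ``prr``, ``bcpnn``, ``combined``) with columns
    ``false_positive_rate`` and ``sensitivity``; by construction the
    combined (conjunction) rule can never flag more than any single method,
    which is asserted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    criteria = criteria or SignalCriteria()
    if drug is None:
        planted_drugs = sorted({d for d, _ in config.planted})
        if not planted_drugs:
            drug = config.drugs[0].name
        else:
            drug = planted_drugs[0]
    null_pts = [e.pt for e in config.events if config.rho(drug, e.pt) <= 1]
    alt_pts = [e.pt for e in config.events if config.rho(drug, e.pt) > 1]

    methods = ("ror", "prr", "bcpnn", "combined")
    fp = {m: 0 for m in methods}
    tp = {m: 0 for m in methods}
    for rep in range(n_reps):
        rep_seed = (seed * 1_000_003 + rep) % (2**31)
        reports, _ = generate_cases(config, seed=rep_seed)
        cases = deduplicate_to_cases(reports)
        tables = build_all_tables(cases, drug, min_a=1)
        for pt_list, counter in ((null_pts, fp), (alt_pts, tp)):
            for pt in pt_list:
                t = tables.get(pt)
                if t is None:
                    continue  # a=0: no method can flag
                r = evaluate_signal(
                    compute_statistics(
                        drug, pt, t, priors=priors,
                        continuity_correction=criteria.chi2_continuity_correction),
                    criteria)
                counter["ror"] += r.ror_positive
                counter["prr"] += r.prr_positive
                counter["bcpnn"] += r.bcpnn_positive
                counter["combined"] += r.combined_signal

    for m in ("ror", "prr", "bcpnn"):
        assert fp["combined"] <= fp[m] and tp["combined"] <= tp[m]

    n_null = len(null_pts) * n_reps
    n_alt = len(alt_pts) * n_reps
    return pd.DataFrame({
        "false_positive_rate": [fp[m] / n_null if n_null else float("nan")
                                for m in methods],
        "sensitivity": [tp[m] / n_alt if n_alt else float("nan")
                        for m in methods],
    }, index=list(methods))
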