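"""Reading, validating and deduplicating spontaneous-report tables.

Spontaneous-report databases such as FAERS are organised around *cases*
(patient-event episodes) that accrue one or more *reports* (versioned
updates) over time.  Each report names one or more drugs, each with a
reporter-assigned role code, and one or more MedDRA preferred terms (PTs)
describing the adverse events.  This module parses two on-disk layouts into
:class:`ReportRecord` objects, collapses them into case-level
:class:`CaseView` objects, and handles the PT -> system-organ-class (SOC)
vocabulary used downstream for aggregation.

Role codes follow FAERS conventions: ``PS`` (primary suspect), ``SS``
(secondary suspect), ``C`` (concomitant), ``I`` (interacting).  When the
same drug appears several times in one report the highest-precedence role
wins (PS > SS > C > I).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

ROLE_CODES = ("PS", "SS", "C", "I")
_ROLE_RANK = {r: i for i, r in enumerate(ROLE_CODES)}

FLAT_CSV_HEADER = [
    "case_id", "report_id", "version_seq", "drug", "role", "pt",
    "sex", "age", "country", "date",
]


class DialectError(ValueError):
    """Unknown or malformed input dialect."""


class UnmappedPTError(KeyError):
    """A preferred term with no SOC mapping in the loaded vocabulary."""

    def __init__(self, pt: str):
        super().__init__(pt)
        self.pt = pt

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"preferred term not in vocabulary: {self.pt!r}"


def normalize_term(s: str) -> str:
    """Collapse internal whitespace and trim; preserves letter case."""
    return " ".join(s.split())


def _key(s: str) -> str:
    """Case-insensitive matching key for drug names and PTs."""
    return normalize_term(s).casefold()


@dataclass(frozen=True)
class DrugEntry:
    """One drug named in a report, with its reporter-assigned role code."""

    name: str
    role: str = "PS"

    def __post_init__(self):
        object.__setattr__(self, "name", normalize_term(self.name))
        if not self.name:
            raise ValueError("drug name empty after normalization")
        if self.role not in _ROLE_RANK:
            raise ValueError(f"unknown role code {self.role!r}")


@dataclass
class ReportRecord:
    """One spontaneous report (a single version of a case)."""

    case_id: str
    report_id: str
    version_seq: int = 0
    receipt_date: date | None = None
    sex: str = "unknown"
    age_years: float | None = None
    country: str = "unknown"
    drugs: list[DrugEntry] = field(default_factory=list)
    events: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.version_seq < 0:
            raise ValueError("version_seq must be non-negative")
        self.events = {normalize_term(pt) for pt in self.events if normalize_term(pt)}
        self.drugs = _collapse_drug_roles(self.drugs)


def _collapse_drug_roles(entries: Iterable[DrugEntry]) -> list[DrugEntry]:
    """Keep one entry per drug name, highest-precedence role, stable order."""
    best: dict[str, DrugEntry] = {}
    order: list[str] = []
    for e in entries:
        k = _key(e.name)
        if k not in best:
            best[k] = e
            order.append(k)
        elif _ROLE_RANK[e.role] < _ROLE_RANK[best[k].role]:
            best[k] = e
    return [best[k] for k in order]


@dataclass
class CaseView:
    """A deduplicated case: union of drug-event content over its reports.

    ``demographics`` come from the report with the highest ``version_seq``
    (ties broken by latest receipt date, then by greatest report id), the
    "most recent version" convention.  ``drug_events`` is the union of
    (drug name, role, PT) triples over every report of the case: a pair seen
    in any version of the case counts for the case.
    """

    case_id: str
    sex: str = "unknown"
    age_years: float | None = None
    country: str = "unknown"
    receipt_date: date | None = None
    drug_events: set[tuple[str, str, str]] = field(default_factory=set)

    def has_drug(self, drug: str, role: str | None = "PS") -> bool:
        """True if *drug* appears in this case, optionally with a given role."""
        dk = _key(drug)
        return any(
            _key(d) == dk and (role is None or r == role)
            for d, r, _ in self.drug_events
        )

    @property
    def pts(self) -> set[str]:
        return {pt for _, _, pt in self.drug_events}


@dataclass(frozen=True)
class VocabularyMap:
    """PT -> SOC lookup with case-insensitive matching.

    Each PT must map to exactly one SOC (MedDRA primary-SOC behaviour is
    approximated by rejecting multi-SOC vocabularies at load).
    """

    entries: Mapping[str, str]
    _index: Mapping[str, str] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        idx: dict[str, str] = {}
        for pt, soc in self.entries.items():
            k = _key(pt)
            soc_n = normalize_term(soc)
            if k in idx and idx[k] != soc_n:
                raise ValueError(f"PT {pt!r} maps to multiple SOCs")
            idx[k] = soc_n
        object.__setattr__(self, "_index", idx)

    def __contains__(self, pt: str) -> bool:
        return _key(pt) in self._index

    def __getitem__(self, pt: str) -> str:
        try:
            return self._index[_key(pt)]
        except KeyError:
            raise UnmappedPTError(pt) from None


def map_pt_to_soc(pt: str, vocab: VocabularyMap) -> str:
    """Return the SOC for *pt*; raises :class:`UnmappedPTError` if absent."""
    return vocab[pt]


def load_vocabulary(path: str | Path) -> VocabularyMap:
    """Load a ``pt,soc`` CSV into a :class:`VocabularyMap`."""
    entries: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "pt" not in reader.fieldnames or "soc" not in reader.fieldnames:
            raise DialectError(f"vocabulary file {path} must have header pt,soc")
        for row in reader:
            pt, soc = normalize_term(row["pt"]), normalize_term(row["soc"])
            if not pt:
                continue
            if _key(pt) in {_key(p) for p in entries} and entries.get(pt) != soc:
                # delegate duplicate detection to VocabularyMap for consistency
                pass
            entries[pt] = soc
    return VocabularyMap(entries)


def load_pt_list(path: str | Path) -> set[str]:
    """Load a one-PT-per-line list; ``#`` starts a comment; blank lines skipped."""
    pts: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                pts.add(normalize_term(line))
    return pts


# alias: exclusion lists share the PT-list format
load_exclusions = load_pt_list


# ---------------------------------------------------------------------------
# report parsing


def _parse_sex(raw: str) -> str:
    s = raw.strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    return "unknown"


def _parse_age(raw: str) -> float | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        v = float(raw)
    except ValueError:
        return None
    return v if v >= 0 else None


def _parse_date(raw: str) -> date | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return date.fromisoformat(raw)
    except ValueError:
        return None


def read_reports(path: str | Path, dialect: str = "flat_csv") -> list[ReportRecord]:
    """Read spontaneous reports from *path*.

    Two dialects are supported:

    ``flat_csv``
        One file; one row per (report, drug, PT) with header
        ``case_id,report_id,version_seq,drug,role,pt,sex,age,country,date``.
    ``faers_ascii``
        A directory holding a dollar-delimited triplet ``demo.txt``
        (case/report/version/demographics), ``drug.txt`` (case/report/
        drug/role) and ``reac.txt`` (case/report/pt), echoing the layout of
        quarterly-extract ASCII files.

    Rows missing a case id or PT are dropped; the drop count is logged.
    A file with a header but no data rows yields an empty list.
    """
    path = Path(path)
    if dialect == "flat_csv":
        return _read_flat_csv(path)
    if dialect == "faers_ascii":
        return _read_faers_ascii(path)
    raise DialectError(f"unknown dialect {dialect!r}")


def _finish_record(meta: dict, drugs: list[DrugEntry], events: set[str]) -> ReportRecord:
    return ReportRecord(
        case_id=meta["case_id"],
        report_id=meta["report_id"],
        version_seq=meta["version_seq"],
        receipt_date=meta["receipt_date"],
        sex=meta["sex"],
        age_years=meta["age_years"],
        country=meta["country"],
        drugs=drugs,
        events=events,
    )


def _read_flat_csv(path: Path) -> list[ReportRecord]:
    groups: dict[str, dict] = {}
    dropped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DialectError(f"{path}: empty file, expected flat_csv header")
        missing = set(FLAT_CSV_HEADER) - set(reader.fieldnames)
        if missing:
            raise DialectError(f"{path}: flat_csv header missing columns {sorted(missing)}")
        for row in reader:
            case_id = normalize_term(row["case_id"] or "")
            pt = normalize_term(row["pt"] or "")
            if not case_id or not pt:
                dropped += 1
                continue
            rid = normalize_term(row["report_id"] or "") or case_id
            g = groups.setdefault(rid, {
                "meta": {
                    "case_id": case_id,
                    "report_id": rid,
                    "version_seq": int(row["version_seq"] or 0),
                    "receipt_date": _parse_date(row["date"] or ""),
                    "sex": _parse_sex(row["sex"] or ""),
                    "age_years": _parse_age(row["age"] or ""),
                    "country": normalize_term(row["country"] or "") or "unknown",
                },
                "drugs": [],
                "events": set(),
            })
            drug = normalize_term(row["drug"] or "")
            if drug:
                role = (row["role"] or "PS").strip().upper()
                if role not in _ROLE_RANK:
                    role = "C"
                g["drugs"].append(DrugEntry(drug, role))
            g["events"].add(pt)
    if dropped:
        logger.warning("%s: dropped %d rows missing case_id or pt", path, dropped)
    records = [_finish_record(g["meta"], g["drugs"], g["events"]) for g in groups.values()]
    records.sort(key=lambda r: (r.case_id, r.version_seq, r.report_id))
    return records


def _find_component(directory: Path, stem: str) -> Path:
    for cand in directory.iterdir():
        if cand.name.lower() in (f"{stem}.txt", f"{stem}.csv"):
            return cand
    raise FileNotFoundError(f"{directory}: missing {stem}.txt component file")


def _read_dollar(path: Path) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise DialectError(f"{path}: empty component file")
    header = lines[0].split("$")
    return header, [ln.split("$") for ln in lines[1:]]


def _read_faers_ascii(path: Path) -> list[ReportRecord]:
    if not path.is_dir():
        raise DialectError(f"faers_ascii dialect expects a directory, got {path}")
    demo_hdr, demo_rows = _read_dollar(_find_component(path, "demo"))
    drug_hdr, drug_rows = _read_dollar(_find_component(path, "drug"))
    reac_hdr, reac_rows = _read_dollar(_find_component(path, "reac"))

    def col(hdr: list[str], name: str) -> int:
        try:
            return [h.strip().lower() for h in hdr].index(name)
        except ValueError:
            raise DialectError(f"component header missing column {name!r}") from None

    di = {c: col(demo_hdr, c) for c in ("case_id", "report_id", "version_seq", "sex", "age", "country", "date")}
    gi = {c: col(drug_hdr, c) for c in ("report_id", "drug", "role")}
    ri = {c: col(reac_hdr, c) for c in ("report_id", "pt")}

    groups: dict[str, dict] = {}
    dropped = 0
    for row in demo_rows:
        case_id = normalize_term(row[di["case_id"]])
        if not case_id:
            dropped += 1
            continue
        rid = normalize_term(row[di["report_id"]]) or case_id
        groups[rid] = {
            "meta": {
                "case_id": case_id,
                "report_id": rid,
                "version_seq": int(row[di["version_seq"]] or 0),
                "receipt_date": _parse_date(row[di["date"]]),
                "sex": _parse_sex(row[di["sex"]]),
                "age_years": _parse_age(row[di["age"]]),
                "country": normalize_term(row[di["country"]]) or "unknown",
            },
            "drugs": [],
            "events": set(),
        }
    for row in drug_rows:
        rid = normalize_term(row[gi["report_id"]])
        drug = normalize_term(row[gi["drug"]])
        if rid in groups and drug:
            role = row[gi["role"]].strip().upper()
            groups[rid]["drugs"].append(DrugEntry(drug, role if role in _ROLE_RANK else "C"))
    for row in reac_rows:
        rid = normalize_term(row[ri["report_id"]])
        pt = normalize_term(row[ri["pt"]])
        if not pt:
            dropped += 1
            continue
        if rid in groups:
            groups[rid]["events"].add(pt)
    # reports with no reaction rows are invalid spontaneous reports
    incomplete = [rid for rid, g in groups.items() if not g["events"]]
    dropped += len(incomplete)
    for rid in incomplete:
        del groups[rid]
    if dropped:
        logger.warning("%s: dropped %d incomplete rows/reports", path, dropped)
    records = [_finish_record(g["meta"], g["drugs"], g["events"]) for g in groups.values()]
    records.sort(key=lambda r: (r.case_id, r.version_seq, r.report_id))
    return records


def write_reports(reports: Sequence[ReportRecord], path: str | Path,
                  dialect: str = "flat_csv") -> None:
    """Write reports in the flat_csv layout (one row per report-drug-PT)."""
    if dialect != "flat_csv":
        raise DialectError(f"write_reports supports flat_csv only, got {dialect!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(FLAT_CSV_HEADER)
        for r in reports:
            drugs = r.drugs or [None]
            for d in drugs:
                for pt in sorted(r.events):
                    w.writerow([
                        r.case_id, r.report_id, r.version_seq,
                        d.name if d else "", d.role if d else "",
                        pt, r.sex,
                        "" if r.age_years is None else r.age_years,
                        r.country,
                        r.receipt_date.isoformat() if r.receipt_date else "",
                    ])


# ---------------------------------------------------------------------------
# case-level deduplication


def deduplicate_to_cases(reports: Iterable[ReportRecord]) -> list[CaseView]:
    """Collapse report versions into one :class:`CaseView` per case id.

    Drug-event content is unioned over every report of a case, so a
    drug-event pair present in any version contributes to the case.
    Demographics follow the latest report version.  Output is sorted by
    case id for determinism.
    """
    by_case: dict[str, list[ReportRecord]] = {}
    for r in reports:
        by_case.setdefault(r.case_id, []).append(r)

    cases: list[CaseView] = []
    for case_id in sorted(by_case):
        group = by_case[case_id]
        latest = max(group, key=lambda r: (
            r.version_seq,
            r.receipt_date or date.min,
            r.report_id,
        ))
        seen: dict[tuple[str, str, str], tuple[str, str, str]] = {}
        for r in group:
            for d in r.drugs:
                for pt in r.events:
                    k = (_key(d.name), d.role, _key(pt))
                    seen.setdefault(k, (d.name, d.role, pt))
        cases.append(CaseView(
            case_id=case_id,
            sex=latest.sex,
            age_years=latest.age_years,
            country=latest.country,
            receipt_date=latest.receipt_date,
            drug_events=set(seen.values()),
        ))
    return cases


def filter_primary_suspect(cases: Sequence[CaseView], drug: str) -> list[CaseView]:
    """Keep cases in which *drug* appears with the primary-suspect role."""
    return [c for c in cases if c.has_drug(drug, role="PS")]


def filter_date_window(cases: Sequence[CaseView], start: date | None = None,
                       end: date | None = None) -> list[CaseView]:
    """Optional receipt-date window filter (inclusive bounds; default off)."""
    out = []
    for c in cases:
        if c.receipt_date is None:
            out.append(c)
            continue
        if start is not None and c.receipt_date < start:
            continue
        if end is not None and c.receipt_date > end:
            continue
        out.append(c)
    return out
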