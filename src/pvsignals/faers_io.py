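"""Ingestion of FAERS-style quarterly ASCII report files.

The FDA Adverse Event Reporting System publishes quarterly extracts as
dollar-sign-delimited ASCII tables. A report (one spontaneous adverse-event
case version) is spread over several files sharing the ``primaryid`` /
``caseid`` identifiers; this module reads the three files needed for
disproportionality screening:

* ``DEMO`` — one row per report version: demographics (age, age unit code,
  sex);
* ``DRUG`` — one row per drug listed on the report (``drugname`` free text);
* ``REAC`` — one row per reaction, coded as a MedDRA preferred term (``pt``).

The pipeline is ``parse_quarter`` (raw rows) → ``link_reports`` (one
:class:`AdverseEventReport` per DEMO row, with drug/reaction sets) →
``deduplicate`` (one report per case: FAERS re-publishes corrected case
versions under new primaryids, and superseded versions must be dropped
before counting).

Counts of everything that is skipped or dropped along the way are kept in a
:class:`ParseLog` so an ingestion run is auditable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from ._util import is_quarter_label, quarter_key

DELIMITER = "$"

DEMO_REQUIRED = ("primaryid", "caseid", "age", "age_cod", "sex")
DRUG_REQUIRED = ("primaryid", "caseid", "drugname")
REAC_REQUIRED = ("primaryid", "caseid", "pt")

#: Years per unit for each FAERS age code.
AGE_CODE_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1429,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

SEX_CODES = {"F": "female", "M": "male"}


class FaersFormatError(ValueError):
    """A file cannot be ingested at all (missing file, missing column)."""


def normalize_age(age_value, age_code) -> float | None:
    """Convert a FAERS (age, age_cod) pair to years, or None.

    Missing value, unknown code, unparseable value and negative results all
    map to None — "unspecified age" is the sink state, matching how the
    stratified tables label reports without usable age.
    """
    if age_value is None or age_code is None:
        return None
    if isinstance(age_value, float) and math.isnan(age_value):
        return None
    code = str(age_code).strip().upper()
    if code not in AGE_CODE_YEARS:
        return None
    try:
        value = float(str(age_value).strip())
    except (TypeError, ValueError):
        return None
    if math.isnan(value):
        return None
    years = value * AGE_CODE_YEARS[code]
    return years if years >= 0 else None


def normalize_sex(sex) -> str:
    if sex is None or (isinstance(sex, float) and math.isnan(sex)):
        return "unspecified"
    return SEX_CODES.get(str(sex).strip().upper(), "unspecified")


def normalize_term(term: str) -> str:
    """Matching key for drug names and preferred terms: uppercase, trimmed."""
    return str(term).strip().upper()


@dataclass
class ParseLog:
    """Counts of rows read, skipped, and reports dropped during ingestion."""

    rows_read: dict[str, int] = field(default_factory=dict)
    rows_skipped: dict[str, int] = field(default_factory=dict)
    orphan_rows_dropped: int = 0
    empty_reports_dropped: int = 0
    duplicate_reports_dropped: int = 0

    def merge(self, other: "ParseLog") -> "ParseLog":
        out = ParseLog(
            rows_read=dict(self.rows_read),
            rows_skipped=dict(self.rows_skipped),
            orphan_rows_dropped=self.orphan_rows_dropped + other.orphan_rows_dropped,
            empty_reports_dropped=self.empty_reports_dropped + other.empty_reports_dropped,
            duplicate_reports_dropped=self.duplicate_reports_dropped
            + other.duplicate_reports_dropped,
        )
        for k, v in other.rows_read.items():
            out.rows_read[k] = out.rows_read.get(k, 0) + v
        for k, v in other.rows_skipped.items():
            out.rows_skipped[k] = out.rows_skipped.get(k, 0) + v
        return out

    def lines(self) -> list[str]:
        out = [f"rows read {name}: {n}" for name, n in sorted(self.rows_read.items())]
        out += [f"rows skipped {name}: {n}" for name, n in sorted(self.rows_skipped.items())]
        out.append(f"orphan rows dropped: {self.orphan_rows_dropped}")
        out.append(f"reports dropped (no drugs or no reactions): {self.empty_reports_dropped}")
        out.append(f"duplicate case versions dropped: {self.duplicate_reports_dropped}")
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return "\n".join(self.lines())


@dataclass
class RawQuarter:
    """Parsed-but-unlinked rows of one quarterly DEMO/DRUG/REAC file set."""

    quarter_label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    log: ParseLog


@dataclass(frozen=True)
class AdverseEventReport:
    """One deduplicated spontaneous report (case)."""

    primaryid: int
    caseid: int
    quarter: str
    age_years: float | None
    sex: str  # "female" | "male" | "unspecified"
    drugs: frozenset[str]  # normalized (uppercase, trimmed) drug names
    reactions: frozenset[str]  # preferred terms, trimmed, original casing

    @property
    def reaction_keys(self) -> frozenset[str]:
        """Uppercased reaction terms, for matching."""
        return frozenset(normalize_term(r) for r in self.reactions)


@dataclass
class ReportSet:
    """A collection of linked reports plus ingestion provenance."""

    reports: list[AdverseEventReport]
    provenance: list[str] = field(default_factory=list)
    log: ParseLog = field(default_factory=ParseLog)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[AdverseEventReport]:
        return iter(self.reports)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "primaryid": [r.primaryid for r in self.reports],
                "caseid": [r.caseid for r in self.reports],
                "quarter": [r.quarter for r in self.reports],
                "age_years": [r.age_years for r in self.reports],
                "sex": [r.sex for r in self.reports],
                "drugs": [r.drugs for r in self.reports],
                "reactions": [r.reactions for r in self.reports],
            }
        )


def _read_delimited(path: Path | str, required: Sequence[str], name: str) -> tuple[pd.DataFrame, int, int]:
    """Read one $-delimited table, keeping only the required columns.

    Rows whose field count differs from the header's are skipped and
    counted — the dialect has no quoting, so an embedded delimiter cannot be
    disambiguated and the row is treated as malformed rather than guessed at.
    (pandas.read_csv cannot express "skip and count short rows", hence the
    explicit line loop.)
    """
    path = Path(path)
    if not path.exists():
        raise FaersFormatError(f"missing {name} file: {path}")
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\r\n")
        header = [h.strip().lower() for h in header_line.split(DELIMITER)]
        for col in required:
            if col not in header:
                raise FaersFormatError(f"{name} file {path} is missing required column '{col}'")
        ncol = len(header)
        idx = {col: header.index(col) for col in required}
        rows: list[list[str]] = []
        read = skipped = 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split(DELIMITER)
            if len(fields) != ncol:
                skipped += 1
                continue
            read += 1
            rows.append([fields[idx[col]] for col in required])
    frame = pd.DataFrame(rows, columns=list(required), dtype=object)
    return frame, read, skipped


def _coerce_ids(frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Parse primaryid/caseid as integers; rows that fail are dropped."""
    if frame.empty:
        out = frame.copy()
        out["primaryid"] = pd.Series(dtype="int64")
        out["caseid"] = pd.Series(dtype="int64")
        return out, 0
    pid = pd.to_numeric(frame["primaryid"], errors="coerce")
    cid = pd.to_numeric(frame["caseid"], errors="coerce")
    ok = pid.notna() & cid.notna()
    out = frame.loc[ok].copy()
    out["primaryid"] = pid[ok].astype("int64")
    out["caseid"] = cid[ok].astype("int64")
    return out, int((~ok).sum())


def parse_quarter(
    demo_path: Path | str,
    drug_path: Path | str,
    reac_path: Path | str,
    quarter_label: str,
) -> RawQuarter:
    """Parse one quarter's DEMO/DRUG/REAC files into raw row tables.

    Raises :class:`FaersFormatError` if a file is missing or a header lacks
    a required column. Malformed rows are skipped and counted in the log.
    """
    if not is_quarter_label(quarter_label):
        raise FaersFormatError(
            f"invalid quarter label {quarter_label!r}; expected e.g. '2020Q1'"
        )
    log = ParseLog()
    tables = {}
    for name, path, required in (
        ("DEMO", demo_path, DEMO_REQUIRED),
        ("DRUG", drug_path, DRUG_REQUIRED),
        ("REAC", reac_path, REAC_REQUIRED),
    ):
        frame, read, skipped = _read_delimited(path, required, name)
        frame, bad_ids = _coerce_ids(frame)
        log.rows_read[name] = read
        log.rows_skipped[name] = skipped + bad_ids
        tables[name] = frame
    return RawQuarter(
        quarter_label=quarter_label,
        demo=tables["DEMO"],
        drug=tables["DRUG"],
        reac=tables["REAC"],
        log=log,
    )


def link_reports(raw: RawQuarter) -> ReportSet:
    """Join DRUG and REAC rows onto DEMO rows by primaryid.

    One :class:`AdverseEventReport` per DEMO row; its drug and reaction sets
    are the union over that report's rows (normalized). DRUG/REAC rows whose
    primaryid has no DEMO row are orphans: counted and dropped. Reports left
    with no drugs or no reactions are likewise dropped and counted — a 2x2
    classification needs both an exposure and an outcome.
    """
    log = replace(
        raw.log,
        rows_read=dict(raw.log.rows_read),
        rows_skipped=dict(raw.log.rows_skipped),
    )
    demo_ids = set(raw.demo["primaryid"].tolist())

    def grouped(frame: pd.DataFrame, col: str, normalize) -> tuple[dict[int, set[str]], int]:
        orphans = 0
        out: dict[int, set[str]] = {}
        for pid, value in zip(frame["primaryid"].tolist(), frame[col].tolist()):
            if pid not in demo_ids:
                orphans += 1
                continue
            norm = normalize(value)
            if not norm:
                continue
            out.setdefault(pid, set()).add(norm)
        return out, orphans

    drugs_by_pid, drug_orphans = grouped(raw.drug, "drugname", normalize_term)
    reacs_by_pid, reac_orphans = grouped(raw.reac, "pt", lambda v: str(v).strip())
    log.orphan_rows_dropped += drug_orphans + reac_orphans

    reports: list[AdverseEventReport] = []
    dropped_empty = 0
    for row in raw.demo.itertuples(index=False):
        drugs = drugs_by_pid.get(row.primaryid, set())
        reactions = reacs_by_pid.get(row.primaryid, set())
        if not drugs or not reactions:
            dropped_empty += 1
            continue
        reports.append(
            AdverseEventReport(
                primaryid=int(row.primaryid),
                caseid=int(row.caseid),
                quarter=raw.quarter_label,
                age_years=normalize_age(row.age, row.age_cod),
                sex=normalize_sex(row.sex),
                drugs=frozenset(drugs),
                reactions=frozenset(reactions),
            )
        )
    log.empty_reports_dropped += dropped_empty
    return ReportSet(reports=reports, provenance=[raw.quarter_label], log=log)


def combine(report_sets: Iterable[ReportSet]) -> ReportSet:
    """Concatenate per-quarter ReportSets (before deduplication)."""
    reports: list[AdverseEventReport] = []
    provenance: list[str] = []
    log = ParseLog()
    for rs in report_sets:
        reports.extend(rs.reports)
        provenance.extend(rs.provenance)
        log = log.merge(rs.log)
    return ReportSet(reports=reports, provenance=provenance, log=log)


def deduplicate(reports: ReportSet) -> ReportSet:
    """Keep one report per caseid: the latest case version.

    FAERS re-publishes corrected versions of a case under a new, larger
    primaryid; the report with the numerically largest primaryid is
    retained, ties broken by the later quarter label. Idempotent.
    """
    best: dict[int, AdverseEventReport] = {}
    for r in reports:
        cur = best.get(r.caseid)
        if cur is None or (r.primaryid, quarter_key(r.quarter)) > (
            cur.primaryid,
            quarter_key(cur.quarter),
        ):
            best[r.caseid] = r
    kept = sorted(best.values(), key=lambda r: (quarter_key(r.quarter), r.caseid))
    log = replace(
        reports.log,
        rows_read=dict(reports.log.rows_read),
        rows_skipped=dict(reports.log.rows_skipped),
    )
    log.duplicate_reports_dropped += len(reports) - len(kept)
    return ReportSet(reports=kept, provenance=list(reports.provenance), log=log)


def quarter_file_paths(directory: Path | str, quarter_label: str) -> tuple[Path, Path, Path]:
    """Locate DEMO/DRUG/REAC files for a quarter in a directory.

    Accepts both the long form DEMO2020Q1.txt (written by the synthetic
    generator) and the FDA short form DEMO20Q1.txt.
    """
    directory = Path(directory)
    year, q = quarter_key(quarter_label)
    paths = []
    for prefix in ("DEMO", "DRUG", "REAC"):
        candidates = [
            directory / f"{prefix}{quarter_label}.txt",
            directory / f"{prefix}{year % 100:02d}Q{q}.txt",
        ]
        found = next((p for p in candidates if p.exists()), None)
        if found is None:
            raise FaersFormatError(
                f"no {prefix} file for quarter {quarter_label} in {directory} "
                f"(tried {', '.join(p.name for p in candidates)})"
            )
        paths.append(found)
    return tuple(paths)  # type: ignore[return-value]


def load_quarters(directory: Path | str, quarter_labels: Sequence[str]) -> ReportSet:
    """Parse, link, and deduplicate every quarter in ``quarter_labels``."""
    sets = []
    for label in quarter_labels:
        demo, drug, reac = quarter_file_paths(directory, label)
        sets.append(link_reports(parse_quarter(demo, drug, reac, label)))
    return deduplicate(combine(sets))
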