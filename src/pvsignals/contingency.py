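"""2x2 contingency structures for drug/event disproportionality screening.

Every statistic in this package is computed from the classic
pharmacovigilance fourfold table over deduplicated cases:

==============  ============  ===================
.               target event  all other events
target drug     a             b
other drugs     c             d
==============  ============  ===================

A case contributes to exactly one cell regardless of how many drug or
reaction rows it listed. Crude, stratified (by sex or age bin), and
Mantel-Haenszel-combined views are provided.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import AdverseEventReport, ReportSet, normalize_term

AGE_BIN_EDGES = (18.0, 25.0, 65.0)
AGE_BIN_LABELS = ("Less than 18", "18-24", "25-64", "65 and older")
UNSPECIFIED_AGE = "Unspecified age"
SEX_LABELS = {"female": "Female", "male": "Male", "unspecified": "Unspecified sex"}


class NotEstimableError(ValueError):
    """A statistic is undefined for this table (zero cell or margin)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts a, b, c, d with derived margins.

    a: target drug & target event; b: target drug, other events;
    c: other drugs, target event; d: other drugs, other events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        """Margin a+b: reports listing the target drug."""
        return self.a + self.b

    @property
    def event_total(self) -> int:
        """Margin a+c: reports listing the target event."""
        return self.a + self.c

    @property
    def other_drug_total(self) -> int:
        return self.c + self.d

    @property
    def other_event_total(self) -> int:
        return self.b + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d
        )

    def corrected(self, delta: float = 0.5) -> "FloatTable":
        """Haldane-Anscombe continuity correction: delta added to each cell."""
        return FloatTable(self.a + delta, self.b + delta, self.c + delta, self.d + delta)

    def to_frame(self, drug_label: str = "Target drug", event_label: str = "Target event") -> pd.DataFrame:
        """Fourfold layout with margins, as printed in study reports."""
        return pd.DataFrame(
            {
                event_label: [self.a, self.c, self.event_total],
                "Other adverse effects": [self.b, self.d, self.other_event_total],
                "Total": [self.drug_total, self.other_drug_total, self.n],
            },
            index=[drug_label, "Other drugs", "Total"],
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "drug_total": self.drug_total,
            "event_total": self.event_total,
            "n": self.n,
        }


@dataclass(frozen=True)
class FloatTable:
    """Continuity-corrected cells (internal use by the statistics layer)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class StratumTable:
    """A labelled fourfold table within a stratification."""

    label: str
    table: ContingencyTable


def _normalized_names(names: Iterable[str]) -> frozenset[str]:
    out = frozenset(normalize_term(n) for n in names if str(n).strip())
    if not out:
        raise ValueError("query requires at least one non-empty name")
    return out


@dataclass(frozen=True)
class DrugQuery:
    """Exact-match (after normalization) set of drug synonyms."""

    names: frozenset[str]

    def __init__(self, names: Iterable[str]):
        object.__setattr__(self, "names", _normalized_names(names))

    def matches(self, report: AdverseEventReport) -> bool:
        return not self.names.isdisjoint(report.drugs)


@dataclass(frozen=True)
class EventQuery:
    """Exact-match set of MedDRA preferred terms.

    Matching is exact on the normalized term: "PANCREATITIS" does not match
    "PANCREATITIS ACUTE" — substring matching would silently change cell a.
    """

    names: frozenset[str]

    def __init__(self, names: Iterable[str]):
        object.__setattr__(self, "names", _normalized_names(names))

    def matches(self, report: AdverseEventReport) -> bool:
        return not self.names.isdisjoint(report.reaction_keys)


def flag_cases(
    reports: ReportSet | Sequence[AdverseEventReport],
    drug: DrugQuery,
    event: EventQuery,
) -> list[tuple[bool, bool]]:
    """Per-report (drug-exposed, event-reported) flags.

    Each report contributes exactly one flag pair however many matching
    drug or reaction rows it carried.
    """
    return [(drug.matches(r), event.matches(r)) for r in reports]


def build_table(
    reports: ReportSet | Sequence[AdverseEventReport],
    drug: DrugQuery,
    event: EventQuery,
) -> ContingencyTable:
    """Crude fourfold table over all reports; cells sum to ``len(reports)``."""
    a = b = c = d = 0
    for exposed, has_event in flag_cases(reports, drug, event):
        if exposed:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def age_bin_label(age_years: float | None) -> str:
    """Left-closed bins [0,18), [18,25), [25,65), [65,inf); None → unspecified."""
    if age_years is None:
        return UNSPECIFIED_AGE
    if age_years < AGE_BIN_EDGES[0]:
        return AGE_BIN_LABELS[0]
    if age_years < AGE_BIN_EDGES[1]:
        return AGE_BIN_LABELS[1]
    if age_years < AGE_BIN_EDGES[2]:
        return AGE_BIN_LABELS[2]
    return AGE_BIN_LABELS[3]


def stratify(
    reports: ReportSet | Sequence[AdverseEventReport],
    drug: DrugQuery,
    event: EventQuery,
    by: str,
) -> list[StratumTable]:
    """Fourfold tables per sex level or age bin.

    The strata partition the reports: their cellwise sum equals the crude
    table. Every stratum of the axis is returned, possibly all-zero.
    """
    if by == "sex":
        labels = ["Female", "Male", "Unspecified sex"]
        key = lambda r: SEX_LABELS[r.sex]
    elif by == "age":
        labels = list(AGE_BIN_LABELS) + [UNSPECIFIED_AGE]
        key = lambda r: age_bin_label(r.age_years)
    else:
        raise ValueError(f"unsupported stratification axis {by!r}; use 'sex' or 'age'")
    groups: dict[str, list[AdverseEventReport]] = {label: [] for label in labels}
    for r in reports:
        groups[key(r)].append(r)
    return [StratumTable(label, build_table(groups[label], drug, event)) for label in labels]


def mantel_haenszel_or(strata: Sequence[StratumTable]) -> float:
    """Mantel-Haenszel combined odds ratio across strata.

    sum_i(a_i d_i / N_i) / sum_i(b_i c_i / N_i); empty strata are skipped.
    Raises :class:`NotEstimableError` when the denominator is zero.
    """
    num = den = 0.0
    for s in strata:
        t = s.table
        if t.n == 0:
            continue
        num += t.a * t.d / t.n
        den += t.b * t.c / t.n
    if den == 0.0:
        raise NotEstimableError("Mantel-Haenszel OR: zero denominator")
    return num / den


def mantel_haenszel_rr(strata: Sequence[StratumTable]) -> float:
    """Mantel-Haenszel combined risk ratio (PRR analogue) across strata.

    sum_i(a_i (c_i+d_i) / N_i) / sum_i(c_i (a_i+b_i) / N_i).
    """
    num = den = 0.0
    for s in strata:
        t = s.table
        if t.n == 0:
            continue
        num += t.a * (t.c + t.d) / t.n
        den += t.c * (t.a + t.b) / t.n
    if den == 0.0:
        raise NotEstimableError("Mantel-Haenszel RR: zero denominator")
    return num / den


def strata_to_frame(strata: Sequence[StratumTable]) -> pd.DataFrame:
    """Tidy per-stratum cell counts (one row per stratum, plus margins)."""
    return pd.DataFrame(
        {
            "stratum": [s.label for s in strata],
            "a": [s.table.a for s in strata],
            "b": [s.table.b for s in strata],
            "c": [s.table.c for s in strata],
            "d": [s.table.d for s in strata],
            "n": [s.table.n for s in strata],
        }
    )


def rank_events(
    reports: ReportSet | Sequence[AdverseEventReport],
    drug: DrugQuery,
    top_k: int,
) -> list[tuple[str, int, "object"]]:
    """Most common reactions among drug-exposed reports, with statistics.

    For each preferred term occurring in at least one exposed report, a
    fourfold table is built (that term vs all others) and the full statistic
    bundle evaluated. Ranked by cell ``a`` descending, ties alphabetical.
    Returns up to ``top_k`` tuples (display term, case count, statistics).
    """
    from .signal_stats import evaluate_signal  # cycle avoidance

    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    reports = list(reports)
    exposed = [drug.matches(r) for r in reports]
    n_total = len(reports)
    n_exposed = sum(exposed)

    # a and a+c per normalized PT; remember first-seen display casing
    a_counts: dict[str, int] = {}
    pt_counts: dict[str, int] = {}
    display: dict[str, str] = {}
    for r, is_exp in zip(reports, exposed):
        for term in r.reactions:
            key = normalize_term(term)
            display.setdefault(key, term.strip())
            pt_counts[key] = pt_counts.get(key, 0) + 1
            if is_exp:
                a_counts[key] = a_counts.get(key, 0) + 1

    ranked = sorted(a_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    out = []
    for key, a in ranked:
        c = pt_counts[key] - a
        b = n_exposed - a
        d = n_total - n_exposed - c
        table = ContingencyTable(a, b, c, d)
        out.append((display[key], a, evaluate_signal(table)))
    return out
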