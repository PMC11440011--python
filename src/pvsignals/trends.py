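"""Per-quarter signal trends: counts, expected vs actual percentages, CIs.

Each calendar quarter is analysed cross-sectionally — the fourfold table is
built from that quarter's reports only, so per-quarter intervals are
independent and wider than the pooled interval on the same data. The
actual percentage is 100·a/N; the expected percentage under independence is
100·((a+b)/N)·((a+c)/N); their ratio is algebraically the observed-to-
expected reporting ratio (EBGM) for the quarter.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._util import quarter_key, quarter_range
from .contingency import ContingencyTable, DrugQuery, EventQuery, build_table
from .signal_stats import (
    DEFAULT_HYPERPARAMETERS,
    BcpnnHyperparameters,
    SignalStatistics,
    evaluate_signal,
)
from .faers_io import ReportSet


@dataclass
class QuarterSeries:
    """Ordered per-quarter counts, percentages and statistics.

    ``frame`` is tidy: one row per quarter with columns quarter, n_total,
    n_drug, n_event, n_drug_event, actual_pct, expected_pct and the point/
    lo/hi columns for each statistic (NaN where not estimable).
    ``statistics`` holds the full per-quarter bundles, ``tables`` the
    per-quarter fourfold tables.
    """

    frame: pd.DataFrame
    tables: dict[str, ContingencyTable]
    statistics: dict[str, SignalStatistics | None]

    @property
    def quarters(self) -> list[str]:
        return self.frame["quarter"].tolist()

    def to_tsv(self, path: Path | str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _percentages(table: ContingencyTable) -> tuple[float | None, float | None]:
    if table.n == 0:
        return None, None
    actual = 100.0 * table.a / table.n
    expected = 100.0 * (table.drug_total / table.n) * (table.event_total / table.n)
    return actual, expected


def quarterly_series(
    reports: ReportSet,
    drug: DrugQuery,
    event: EventQuery,
    hp: BcpnnHyperparameters = DEFAULT_HYPERPARAMETERS,
) -> QuarterSeries:
    """Build the full per-quarter series over the span of the data.

    The span runs from the earliest to the latest quarter present among the
    reports (plus any ingested-but-empty quarters in the provenance);
    quarters with no reports get zero counts and no statistics.
    """
    labels = {r.quarter for r in reports} | set(reports.provenance)
    if not labels:
        raise ValueError("cannot build a quarterly series from an empty report set")
    ordered = sorted(labels, key=quarter_key)
    span = quarter_range(ordered[0], ordered[-1])

    by_quarter: dict[str, list] = {q: [] for q in span}
    for r in reports:
        by_quarter[r.quarter].append(r)

    rows = []
    tables: dict[str, ContingencyTable] = {}
    stats: dict[str, SignalStatistics | None] = {}
    for q in span:
        table = build_table(by_quarter[q], drug, event)
        tables[q] = table
        st = evaluate_signal(table, hp) if table.n > 0 else None
        stats[q] = st
        actual, expected = _percentages(table)
        row = {
            "quarter": q,
            "n_total": table.n,
            "n_drug": table.drug_total,
            "n_event": table.event_total,
            "n_drug_event": table.a,
            "actual_pct": actual,
            "expected_pct": expected,
        }
        for name in ("ror", "prr", "ic2"):
            est = getattr(st, name, None) if st is not None else None
            row[name] = est.value if est is not None else None
            row[f"{name}_lo"] = est.lo if est is not None else None
            row[f"{name}_hi"] = est.hi if est is not None else None
        row["ebgm"] = st.ebgm if st is not None else None
        rows.append(row)
    return QuarterSeries(frame=pd.DataFrame(rows), tables=tables, statistics=stats)


def expected_vs_actual(series: QuarterSeries) -> pd.DataFrame:
    """Per-quarter (actual_pct, expected_pct) pairs.

    Their ratio, where defined, equals the quarter's observed-to-expected
    reporting ratio exactly.
    """
    return series.frame[["quarter", "actual_pct", "expected_pct"]].copy()
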