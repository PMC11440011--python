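"""Model/Results front end for disproportionality analysis.

The estimation surface follows the fitted-model idiom: a
:class:`DisproportionalityModel` is constructed from data (a fourfold
table, raw cell counts, or a linked report set plus drug/event queries),
``fit()`` runs the estimators, and the returned
:class:`DisproportionalityResults` carries the estimates, their intervals,
signal flags and a printable ``summary()``. Stratified fits additionally
carry per-stratum tables and the Mantel-Haenszel combined ratios;
report-backed fits expose the per-quarter trend series.

>>> res = DisproportionalityModel.from_counts(79, 11617, 13673, 7499604).fit()
>>> round(res.ror.value, 2)
3.73
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .contingency import (
    ContingencyTable,
    DrugQuery,
    EventQuery,
    NotEstimableError,
    StratumTable,
    build_table,
    mantel_haenszel_or,
    mantel_haenszel_rr,
    strata_to_frame,
    stratify,
)
from .faers_io import ReportSet
from .signal_stats import (
    DEFAULT_HYPERPARAMETERS,
    BcpnnHyperparameters,
    IntervalEstimate,
    SignalStatistics,
    evaluate_signal,
)
from .trends import QuarterSeries, quarterly_series


class DisproportionalityModel:
    """Drug/event disproportionality over a 2x2 reporting table.

    Parameters
    ----------
    table:
        The fourfold table of case counts. Use :meth:`from_reports` to
        derive it (and keep stratification/trend capability) from a linked,
        deduplicated :class:`~pvsignals.faers_io.ReportSet`.
    hp:
        BCPNN prior pseudo-counts and interval multiplier for the
        information component.
    """

    def __init__(
        self,
        table: ContingencyTable,
        hp: BcpnnHyperparameters = DEFAULT_HYPERPARAMETERS,
        *,
        reports: ReportSet | None = None,
        drug: DrugQuery | None = None,
        event: EventQuery | None = None,
    ):
        self.table = table
        self.hp = hp
        self.reports = reports
        self.drug = drug
        self.event = event

    @classmethod
    def from_counts(
        cls, a: int, b: int, c: int, d: int, hp: BcpnnHyperparameters = DEFAULT_HYPERPARAMETERS
    ) -> "DisproportionalityModel":
        return cls(ContingencyTable(a, b, c, d), hp)

    @classmethod
    def from_reports(
        cls,
        reports: ReportSet,
        drug: DrugQuery,
        event: EventQuery,
        hp: BcpnnHyperparameters = DEFAULT_HYPERPARAMETERS,
    ) -> "DisproportionalityModel":
        table = build_table(reports, drug, event)
        return cls(table, hp, reports=reports, drug=drug, event=event)

    def fit(
        self,
        stratify_by: str | None = None,
        *,
        correct_zero_cells: bool = False,
    ) -> "DisproportionalityResults":
        """Compute the statistics; optionally a stratified (MH) analysis.

        ``stratify_by`` is "sex" or "age" and requires the model to have
        been built from reports.
        """
        statistics = evaluate_signal(self.table, self.hp, correct_zero_cells=correct_zero_cells)
        strata = mh_or = mh_rr = None
        if stratify_by is not None:
            if self.reports is None:
                raise ValueError("stratified fit requires a report-backed model")
            strata = stratify(self.reports, self.drug, self.event, by=stratify_by)
            try:
                mh_or = mantel_haenszel_or(strata)
            except NotEstimableError:
                mh_or = None
            try:
                mh_rr = mantel_haenszel_rr(strata)
            except NotEstimableError:
                mh_rr = None
        return DisproportionalityResults(
            model=self,
            statistics=statistics,
            stratified_by=stratify_by,
            strata=strata,
            mh_ror=mh_or,
            mh_prr=mh_rr,
        )


@dataclass
class DisproportionalityResults:
    """Fitted estimates, intervals, flags, and optional stratified view."""

    model: DisproportionalityModel
    statistics: SignalStatistics
    stratified_by: str | None = None
    strata: list[StratumTable] | None = None
    mh_ror: float | None = None
    mh_prr: float | None = None

    # -- flat accessors ------------------------------------------------
    @property
    def table(self) -> ContingencyTable:
        return self.model.table

    @property
    def ror(self) -> IntervalEstimate | None:
        return self.statistics.ror

    @property
    def prr(self) -> IntervalEstimate | None:
        return self.statistics.prr

    @property
    def ebgm(self) -> float | None:
        return self.statistics.ebgm

    @property
    def ic2(self) -> IntervalEstimate | None:
        return self.statistics.ic2

    def strata_frame(self) -> pd.DataFrame:
        if self.strata is None:
            raise ValueError("results were not stratified")
        return strata_to_frame(self.strata)

    def quarterly(self) -> QuarterSeries:
        """Per-quarter trend series (report-backed models only)."""
        m = self.model
        if m.reports is None:
            raise ValueError("quarterly series requires a report-backed model")
        return quarterly_series(m.reports, m.drug, m.event, m.hp)

    def summary(self, precision: int = 2) -> str:
        """Human-readable fit summary in the style of fitted-model reports."""
        t = self.table
        lines = [
            "Disproportionality analysis",
            "=" * 60,
            f"Contingency table: a={t.a}  b={t.b}  c={t.c}  d={t.d}  (N={t.n})",
            "",
            f"{'statistic':<10}{'estimate':>10}{'95% CI':>20}{'criterion':>10}{'signal':>8}",
            "-" * 60,
        ]

        def row(name: str, est: IntervalEstimate | None, criterion: str, flag):
            if est is None:
                lines.append(f"{name:<10}{'n.e.':>10}{'':>20}{criterion:>10}{'':>8}")
                return
            ci = f"({round_half_up(est.lo, precision)}, {round_half_up(est.hi, precision)})"
            flag_s = "" if flag is None else ("yes" if flag else "no")
            lines.append(
                f"{name:<10}{round_half_up(est.value, precision):>10}{ci:>20}"
                f"{criterion:>10}{flag_s:>8}"
            )

        s = self.statistics
        row("ROR", s.ror, "CI > 1", s.ror_signal)
        row("PRR", s.prr, "CI > 1", s.prr_signal)
        if s.ebgm is None:
            lines.append(f"{'EBGM':<10}{'n.e.':>10}")
        else:
            lines.append(f"{'EBGM':<10}{round_half_up(s.ebgm, precision):>10}")
        row("IC2", s.ic2, "CI > 0", s.ic2_signal)
        if s.continuity_corrected:
            lines.append("note: Haldane-Anscombe +0.5 correction applied (zero cell)")
        if self.stratified_by is not None:
            lines.append("")
            lines.append(f"Mantel-Haenszel combination over {self.stratified_by} strata")
            lines.append("-" * 60)
            mh_or = "n.e." if self.mh_ror is None else round_half_up(self.mh_ror, precision)
            mh_rr = "n.e." if self.mh_prr is None else round_half_up(self.mh_prr, precision)
            lines.append(f"MH ROR: {mh_or}    MH PRR: {mh_rr}")
            for st in self.strata:
                tt = st.table
                lines.append(
                    f"  {st.label:<18} a={tt.a:>6} b={tt.b:>9} c={tt.c:>9} d={tt.d:>12}"
                )
        return "\n".join(lines)


def mantel_haenszel_fit(
    strata: Sequence[StratumTable],
) -> tuple[float, float]:
    """Convenience: (MH odds ratio, MH risk ratio) from pre-built strata."""
    return mantel_haenszel_or(strata), mantel_haenszel_rr(strata)
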