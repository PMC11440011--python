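"""Disproportionality statistics with confidence intervals and signal flags.

Four standard pharmacovigilance screening statistics over a fourfold table:

* ROR — reporting odds ratio (a/c)/(b/d), Wald 95% CI on the log scale;
* PRR — proportional reporting ratio (a/(a+b))/(c/(c+d)), same CI form;
* EBGM — here the observed-to-expected relative reporting ratio
  a·N/((a+b)(a+c)); no interval is attached to it;
* IC2 — Bayesian (BCPNN) information component, the posterior expectation
  of log2 of the observed-to-expected ratio under Dirichlet-style priors on
  the cell probabilities, with a credibility interval from the posterior
  variance. The priors regularize empty cells, so the IC is defined even
  when a = 0.

A pair is conventionally flagged as a signal when the ROR/PRR interval lies
entirely above 1, or the IC interval entirely above 0. A signal is a
screening flag over a spontaneous-reporting system, not evidence of
causation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up
from .contingency import ContingencyTable, FloatTable, NotEstimableError

Z_WALD = 1.96  # two-sided 95% normal quantile for the log-Wald intervals


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with lower/upper interval bounds."""

    value: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.value <= self.hi):
            raise ValueError("interval bounds do not bracket the estimate")


@dataclass(frozen=True)
class BcpnnHyperparameters:
    """Prior pseudo-counts for the BCPNN information component.

    alpha1/beta1 are priors on the drug and event margins, alpha/beta the
    corresponding denominators, gamma11 the prior on the joint cell. The
    defaults give the symmetric IC prior centred on independence. z_ic
    scales the credibility interval in posterior-SD units; 2 by default.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0
    z_ic: float = 2.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha", "beta", "gamma11", "z_ic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be > 0")


DEFAULT_HYPERPARAMETERS = BcpnnHyperparameters()


def _working_cells(table: ContingencyTable, correct_zero_cells: bool):
    """Cells for ROR/PRR, optionally Haldane-Anscombe corrected.

    The +0.5 correction is applied only when some cell is zero; the second
    return value says whether it was.
    """
    if correct_zero_cells and table.has_zero_cell:
        return table.corrected(0.5), True
    return table, False


def _log_wald_interval(point: float, a, b, c, d) -> IntervalEstimate:
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_point = math.log(point)
    return IntervalEstimate(
        value=point,
        lo=math.exp(log_point - Z_WALD * se),
        hi=math.exp(log_point + Z_WALD * se),
    )


def ror(table: ContingencyTable, *, correct_zero_cells: bool = False) -> IntervalEstimate:
    """Reporting odds ratio with 95% log-Wald CI.

    Raises :class:`NotEstimableError` on a zero cell unless
    ``correct_zero_cells`` applies the +0.5 correction.
    """
    t, _ = _working_cells(table, correct_zero_cells)
    a, b, c, d = t.cells()
    if min(a, b, c, d) <= 0:
        raise NotEstimableError("ROR requires all four cells > 0")
    point = (a / c) / (b / d)
    return _log_wald_interval(point, a, b, c, d)


def prr(table: ContingencyTable, *, correct_zero_cells: bool = False) -> IntervalEstimate:
    """Proportional reporting ratio with 95% log-Wald CI (same SE form as ROR)."""
    t, _ = _working_cells(table, correct_zero_cells)
    a, b, c, d = t.cells()
    if min(a, b, c, d) <= 0:
        raise NotEstimableError("PRR requires all four cells > 0")
    point = (a / (a + b)) / (c / (c + d))
    return _log_wald_interval(point, a, b, c, d)


def ebgm_rrr(table: ContingencyTable | FloatTable) -> float:
    """Observed-to-expected relative reporting ratio a·N/((a+b)(a+c)).

    Equals 1 exactly under row/column independence. No interval.
    """
    a, b, c, d = table.cells()
    n = a + b + c + d
    if (a + b) <= 0 or (a + c) <= 0:
        raise NotEstimableError("EBGM requires positive drug and event margins")
    return a * n / ((a + b) * (a + c))


def ic2_bcpnn(
    table: ContingencyTable,
    hp: BcpnnHyperparameters = DEFAULT_HYPERPARAMETERS,
) -> IntervalEstimate:
    """BCPNN information component: posterior mean and credibility interval.

    With prior pseudo-counts from ``hp``, the posterior expectation is

        E(IC) = log2[ (a+g11)(N+alpha)(N+beta) /
                      ((N+gamma)(a+b+alpha1)(a+c+beta1)) ],

    where gamma = g11(N+alpha)(N+beta)/((a+b+alpha1)(a+c+beta1)) keeps the
    prior centred on independence, and the posterior variance is the
    standard three-term delta-method expression (in bits). The interval is
    E(IC) ± z_ic·sqrt(V(IC)). For proportionally growing cells E(IC)
    converges to log2 of the observed-to-expected ratio; the difference is
    the Bayesian shrinkage toward IC = 0.
    """
    a = float(table.a)
    n = float(table.n)
    if n <= 0:
        raise NotEstimableError("IC requires a non-empty table")
    row = float(table.a + table.b)  # a+b
    col = float(table.a + table.c)  # a+c
    gamma = hp.gamma11 * (n + hp.alpha) * (n + hp.beta) / ((row + hp.alpha1) * (col + hp.beta1))
    expectation = math.log2(
        (a + hp.gamma11)
        * (n + hp.alpha)
        * (n + hp.beta)
        / ((n + gamma) * (row + hp.alpha1) * (col + hp.beta1))
    )
    ln2_sq = math.log(2.0) ** 2
    variance = (
        (n - a + gamma - hp.gamma11) / ((a + hp.gamma11) * (1.0 + n + gamma))
        + (n - row + hp.alpha - hp.alpha1) / ((row + hp.alpha1) * (1.0 + n + hp.alpha))
        + (n - col + hp.beta - hp.beta1) / ((col + hp.beta1) * (1.0 + n + hp.beta))
    ) / ln2_sq
    half = hp.z_ic * math.sqrt(variance)
    return IntervalEstimate(value=expectation, lo=expectation - half, hi=expectation + half)


@dataclass(frozen=True)
class SignalStatistics:
    """Bundle of the four statistics for one fourfold table.

    Components that are not estimable for the table are None — never a
    silent zero or NaN — and their signal flag is likewise None.
    """

    ror: IntervalEstimate | None
    prr: IntervalEstimate | None
    ebgm: float | None
    ic2: IntervalEstimate | None
    continuity_corrected: bool = False

    @property
    def ror_signal(self) -> bool | None:
        return None if self.ror is None else self.ror.lo > 1.0

    @property
    def prr_signal(self) -> bool | None:
        return None if self.prr is None else self.prr.lo > 1.0

    @property
    def ic2_signal(self) -> bool | None:
        return None if self.ic2 is None else self.ic2.lo > 0.0

    def to_frame(self, precision: int | None = None) -> pd.DataFrame:
        """Report layout: statistic, estimate, CI, criterion, flag."""

        def fmt(x: float | None) -> float | None:
            if x is None:
                return None
            return round_half_up(x, precision) if precision is not None else x

        rows = [
            (
                "ROR",
                fmt(None if self.ror is None else self.ror.value),
                fmt(None if self.ror is None else self.ror.lo),
                fmt(None if self.ror is None else self.ror.hi),
                "CI > 1",
                self.ror_signal,
            ),
            (
                "PRR",
                fmt(None if self.prr is None else self.prr.value),
                fmt(None if self.prr is None else self.prr.lo),
                fmt(None if self.prr is None else self.prr.hi),
                "CI > 1",
                self.prr_signal,
            ),
            ("EBGM", fmt(self.ebgm), None, None, "", None),
            (
                "IC2",
                fmt(None if self.ic2 is None else self.ic2.value),
                fmt(None if self.ic2 is None else self.ic2.lo),
                fmt(None if self.ic2 is None else self.ic2.hi),
                "CI > 0",
                self.ic2_signal,
            ),
        ]
        return pd.DataFrame(
            rows, columns=["statistic", "estimate", "ci_lo", "ci_hi", "criterion", "signal"]
        )

    def to_dict(self) -> dict:
        def triple(est: IntervalEstimate | None):
            return None if est is None else {"value": est.value, "lo": est.lo, "hi": est.hi}

        return {
            "ror": triple(self.ror),
            "prr": triple(self.prr),
            "ebgm": self.ebgm,
            "ic2": triple(self.ic2),
            "ror_signal": self.ror_signal,
            "prr_signal": self.prr_signal,
            "ic2_signal": self.ic2_signal,
            "continuity_corrected": self.continuity_corrected,
        }


def evaluate_signal(
    table: ContingencyTable,
    hp: BcpnnHyperparameters = DEFAULT_HYPERPARAMETERS,
    *,
    correct_zero_cells: bool = False,
) -> SignalStatistics:
    """Compute all four statistics, tolerating not-estimable components."""
    corrected = correct_zero_cells and table.has_zero_cell
    try:
        ror_est = ror(table, correct_zero_cells=correct_zero_cells)
    except NotEstimableError:
        ror_est = None
    try:
        prr_est = prr(table, correct_zero_cells=correct_zero_cells)
    except NotEstimableError:
        prr_est = None
    try:
        ebgm_est = ebgm_rrr(table)
    except NotEstimableError:
        ebgm_est = None
    try:
        ic_est = ic2_bcpnn(table, hp)
    except NotEstimableError:
        ic_est = None
    return SignalStatistics(
        ror=ror_est,
        prr=prr_est,
        ebgm=ebgm_est,
        ic2=ic_est,
        continuity_corrected=corrected,
    )
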