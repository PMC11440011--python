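"""Packaged worked-example tables: teduglutide and pancreatitis in FAERS.

The published disproportionality study of teduglutide-associated
pancreatitis (FAERS 2020 Q1 - 2024 Q1) printed its crude and stratified
fourfold tables and the demographics of the exposed cohort; those tables
are shipped here as tiny TSVs so the statistics layer can be demonstrated
and regression-tested without any FAERS download.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from ..contingency import ContingencyTable, StratumTable

__all__ = [
    "teduglutide_pancreatitis_crude",
    "teduglutide_pancreatitis_sex_strata",
    "teduglutide_pancreatitis_age_strata",
    "teduglutide_demographics",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def teduglutide_pancreatitis_crude() -> ContingencyTable:
    """Crude fourfold table: 79 / 11,617 / 13,673 / 7,499,604 (N=7,524,973)."""
    row = _read("teduglutide_pancreatitis_crude.tsv").iloc[0]
    return ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d))


def _strata(name: str) -> list[StratumTable]:
    frame = _read(name)
    return [
        StratumTable(r.stratum, ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d)))
        for r in frame.itertuples(index=False)
    ]


def teduglutide_pancreatitis_sex_strata() -> list[StratumTable]:
    """Sex-stratified fourfold tables (Female / Male / Unspecified sex)."""
    return _strata("teduglutide_pancreatitis_sex_strata.tsv")


def teduglutide_pancreatitis_age_strata() -> list[StratumTable]:
    """Age-stratified fourfold tables over the study's five age bins."""
    return _strata("teduglutide_pancreatitis_age_strata.tsv")


def teduglutide_demographics() -> pd.DataFrame:
    """Age-bin and sex counts among teduglutide reports (known values only)."""
    return _read("teduglutide_demographics.tsv")
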