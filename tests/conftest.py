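"""Shared fixtures: study tables, handwritten file sets, random report sets."""
from __future__ import annotations

import numpy as np
import pytest

from pvsignals import AdverseEventReport, ContingencyTable, DrugQuery, EventQuery, ReportSet
from pvsignals.datasets import (
    teduglutide_pancreatitis_age_strata,
    teduglutide_pancreatitis_crude,
    teduglutide_pancreatitis_sex_strata,
)

TARGET_DRUG = "TEDUGLUTIDE"
TARGET_EVENT = "Pancreatitis"


@pytest.fixture(scope="session")
def crude_table() -> ContingencyTable:
    return teduglutide_pancreatitis_crude()


@pytest.fixture(scope="session")
def sex_strata():
    return teduglutide_pancreatitis_sex_strata()


@pytest.fixture(scope="session")
def age_strata():
    return teduglutide_pancreatitis_age_strata()


@pytest.fixture(scope="session")
def drug_query() -> DrugQuery:
    return DrugQuery([TARGET_DRUG, "GATTEX"])


@pytest.fixture(scope="session")
def event_query() -> EventQuery:
    return EventQuery([TARGET_EVENT])


def make_report(
    primaryid: int,
    caseid: int,
    quarter: str = "2020Q1",
    age: float | None = 40.0,
    sex: str = "female",
    drugs=("ASPIRIN",),
    reactions=("Nausea",),
) -> AdverseEventReport:
    return AdverseEventReport(
        primaryid=primaryid,
        caseid=caseid,
        quarter=quarter,
        age_years=age,
        sex=sex,
        drugs=frozenset(str(d).strip().upper() for d in drugs),
        reactions=frozenset(str(r).strip() for r in reactions),
    )


def random_report_set(
    n: int,
    seed: int,
    quarters=("2020Q1", "2020Q2", "2020Q3", "2020Q4"),
    p_drug: float = 0.3,
    p_event: float = 0.3,
) -> ReportSet:
    """Small random ReportSet with dense drug/event flags for oracle tests."""
    rng = np.random.default_rng(seed)
    extra_drugs = ["OMEPRAZOLE", "METFORMIN", "ASPIRIN"]
    extra_pts = ["Nausea", "Headache", "Rash", "Diarrhoea"]
    reports = []
    for i in range(n):
        drugs = set(rng.choice(extra_drugs, size=rng.integers(1, 3), replace=False))
        if rng.random() < p_drug:
            drugs.add(TARGET_DRUG)
        reactions = set(rng.choice(extra_pts, size=rng.integers(1, 3), replace=False))
        if rng.random() < p_event:
            reactions.add(TARGET_EVENT)
        age = None if rng.random() < 0.2 else float(rng.uniform(0, 90))
        sex = str(rng.choice(["female", "male", "unspecified"], p=[0.5, 0.4, 0.1]))
        reports.append(
            make_report(
                primaryid=1000 + i,
                caseid=1000 + i,
                quarter=str(rng.choice(quarters)),
                age=age,
                sex=sex,
                drugs=drugs,
                reactions=reactions,
            )
        )
    return ReportSet(reports=reports, provenance=list(quarters))


def write_quarter_files(directory, quarter, demo_rows, drug_rows, reac_rows):
    """Write raw $-delimited rows (given as strings) under a directory."""
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"DEMO{quarter}.txt").write_text(
        "primaryid$caseid$age$age_cod$sex\n" + "".join(r + "\n" for r in demo_rows)
    )
    (directory / f"DRUG{quarter}.txt").write_text(
        "primaryid$caseid$drugname\n" + "".join(r + "\n" for r in drug_rows)
    )
    (directory / f"REAC{quarter}.txt").write_text(
        "primaryid$caseid$pt\n" + "".join(r + "\n" for r in reac_rows)
    )
    return (
        directory / f"DEMO{quarter}.txt",
        directory / f"DRUG{quarter}.txt",
        directory / f"REAC{quarter}.txt",
    )


@pytest.fixture
def three_report_quarter(tmp_path):
    """Three linked reports, one extra DRUG row, duplicated drug listing."""
    return write_quarter_files(
        tmp_path,
        "2020Q1",
        demo_rows=[
            "1001$100$40$YR$F",
            "1002$101$240$MON$M",
            "1003$102$$$",
        ],
        drug_rows=[
            "1001$100$Gattex ",
            "1001$100$GATTEX",
            "1002$101$ASPIRIN",
            "1003$102$OMEPRAZOLE",
        ],
        reac_rows=[
            "1001$100$Pancreatitis",
            "1001$100$Nausea",
            "1002$101$Rash",
            "1003$102$Headache",
            "1003$102$Diarrhoea",
        ],
    )
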