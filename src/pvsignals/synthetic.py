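"""Synthetic spontaneous-report generator with known ground truth.

Real FAERS extracts are multi-gigabyte downloads; this module fabricates
quarterly DEMO/DRUG/REAC file sets in the exact dialect the ingestion layer
reads, with a configurable drug-event association strength, so the whole
pipeline is exercisable and its estimators checkable against a known
injected relative risk.

The generative model is deliberately simple: each case independently lists
the target drug with probability ``drug_prevalence``; it reports the target
event with probability ``event_background_rate`` (times ``relative_risk``
when exposed, capped at 1). Background drugs and reactions are drawn from
toy vocabularies independently of exposure — there is no confounding unless
the optional ``confounder_strength`` hook is enabled, which inflates both
exposure prevalence and event rate in the oldest age group so that crude
and age-adjusted (Mantel-Haenszel) estimates separate. Demographics mimic
the study population: a bimodal age mix (pediatric and older-adult modes)
with a missing fraction, and a female-leaning sex mix. A configurable
fraction of cases is emitted twice under distinct primaryids to exercise
deduplication.

Defaults mirror the study's marginal reporting frequencies at desk scale:
seventeen quarters, rare exposure (~0.16%) and rare event (~0.18%), an
injected relative risk of 3.7.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import quarter_range
from .faers_io import AdverseEventReport, ParseLog, ReportSet

TARGET_DRUG = "TEDUGLUTIDE"
TARGET_EVENT = "Pancreatitis"

# Toy background vocabularies; weights fall off roughly like a Zipf law,
# echoing how a handful of terms dominate spontaneous reporting.
BACKGROUND_PTS = (
    "Nausea", "Diarrhoea", "Headache", "Vomiting", "Fatigue", "Dizziness",
    "Pyrexia", "Rash", "Abdominal pain", "Weight decreased", "Dehydration",
    "Arthralgia", "Dyspnoea", "Pruritus", "Insomnia", "Constipation",
    "Abdominal distension", "Oedema peripheral", "Anxiety", "Cough",
)
BACKGROUND_DRUGS = (
    "OMEPRAZOLE", "ASPIRIN", "METFORMIN", "LISINOPRIL", "ATORVASTATIN",
    "LEVOTHYROXINE", "AMLODIPINE", "PREDNISONE", "IBUPROFEN", "GABAPENTIN",
    "FUROSEMIDE", "PANTOPRAZOLE", "SERTRALINE", "ONDANSETRON", "WARFARIN",
)


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters for the report generator.

    Probabilities are per report; ``relative_risk`` multiplies the event
    probability of exposed reports (capped at 1). ``duplicate_rate`` is the
    fraction of cases emitted a second time under a new primaryid.
    """

    n_reports_per_quarter: int = 10_000
    quarters: tuple[str, ...] = tuple(quarter_range("2020Q1", "2024Q1"))
    drug_prevalence: float = 0.0016
    event_background_rate: float = 0.0018
    relative_risk: float = 3.7
    sex_probs: tuple[float, float, float] = (0.55, 0.40, 0.05)  # F, M, unspecified
    age_missing_prob: float = 0.32
    pediatric_weight: float = 0.25  # of age-known reports
    duplicate_rate: float = 0.10
    confounder_strength: float = 0.0  # >0: age>=65 inflates exposure and event rates
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.drug_prevalence,
            self.event_background_rate,
            self.duplicate_rate,
            self.age_missing_prob,
            self.pediatric_weight,
            *self.sex_probs,
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9:
            raise ValueError("sex_probs must sum to 1")
        if self.relative_risk <= 0:
            raise ValueError("relative_risk must be > 0")
        if self.n_reports_per_quarter < 1 or not self.quarters:
            raise ValueError("need at least one report and one quarter")


@dataclass
class GroundTruth:
    """Latent per-case exposure/event indicators and the config used."""

    frame: pd.DataFrame  # caseid, quarter, exposed, event, sex, age_years
    config: SynthConfig

    def crude_cells(self) -> tuple[int, int, int, int]:
        e = self.frame["exposed"].to_numpy(bool)
        v = self.frame["event"].to_numpy(bool)
        return (
            int((e & v).sum()),
            int((e & ~v).sum()),
            int((~e & v).sum()),
            int((~e & ~v).sum()),
        )


def _draw_ages(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    """Bimodal age mixture; NaN encodes missing age."""
    ages = np.full(n, np.nan)
    known = rng.random(n) >= cfg.age_missing_prob
    n_known = int(known.sum())
    pediatric = rng.random(n_known) < cfg.pediatric_weight
    vals = np.where(
        pediatric,
        np.clip(rng.normal(8.0, 5.0, n_known), 0.0, 17.9),
        np.clip(rng.normal(55.0, 16.0, n_known), 18.0, 100.0),
    )
    ages[known] = np.round(vals, 1)
    return ages


def generate_reports(config: SynthConfig) -> tuple[ReportSet, GroundTruth]:
    """Draw a full ReportSet (including duplicate case versions) plus truth.

    Fully deterministic given the config (which includes the seed).
    """
    rng = np.random.default_rng(config.seed)
    pt_weights = 1.0 / np.arange(1, len(BACKGROUND_PTS) + 1)
    pt_weights /= pt_weights.sum()
    drug_weights = 1.0 / np.arange(1, len(BACKGROUND_DRUGS) + 1)
    drug_weights /= drug_weights.sum()

    reports: list[AdverseEventReport] = []
    truth_rows = []
    caseid = 100_000
    for quarter in config.quarters:
        n = config.n_reports_per_quarter
        ages = _draw_ages(rng, n, config)
        sexes = rng.choice(("female", "male", "unspecified"), size=n, p=config.sex_probs)
        elderly = ~np.isnan(ages) & (ages >= 65.0)
        boost = 1.0 + config.confounder_strength
        p_exp = np.where(elderly, min(1.0, config.drug_prevalence * boost), config.drug_prevalence)
        exposed = rng.random(n) < p_exp
        base_rate = np.where(
            elderly,
            min(1.0, config.event_background_rate * boost),
            config.event_background_rate,
        )
        p_event = np.minimum(1.0, base_rate * np.where(exposed, config.relative_risk, 1.0))
        has_event = rng.random(n) < p_event
        n_extra_pts = rng.integers(1, 5, size=n)
        n_extra_drugs = rng.integers(0, 4, size=n)

        for i in range(n):
            caseid += 1
            drugs = set(
                rng.choice(BACKGROUND_DRUGS, size=n_extra_drugs[i], replace=False, p=drug_weights)
            )
            if exposed[i]:
                drugs.add(TARGET_DRUG)
            if not drugs:  # every report lists at least one drug
                drugs.add(str(rng.choice(BACKGROUND_DRUGS, p=drug_weights)))
            reactions = set(
                rng.choice(BACKGROUND_PTS, size=n_extra_pts[i], replace=False, p=pt_weights)
            )
            if has_event[i]:
                reactions.add(TARGET_EVENT)
            reports.append(
                AdverseEventReport(
                    primaryid=caseid * 100 + 1,
                    caseid=caseid,
                    quarter=quarter,
                    age_years=None if math.isnan(ages[i]) else float(ages[i]),
                    sex=str(sexes[i]),
                    drugs=frozenset(drugs),
                    reactions=frozenset(reactions),
                )
            )
            truth_rows.append(
                {
                    "caseid": caseid,
                    "quarter": quarter,
                    "exposed": bool(exposed[i]),
                    "event": bool(has_event[i]),
                    "sex": str(sexes[i]),
                    "age_years": None if math.isnan(ages[i]) else float(ages[i]),
                }
            )

    # Duplicate case versions: identical content, next version number.
    n_dup = int(round(config.duplicate_rate * len(reports)))
    if n_dup:
        dup_idx = rng.choice(len(reports), size=n_dup, replace=False)
        for i in sorted(dup_idx):
            r = reports[i]
            reports.append(replace(r, primaryid=r.primaryid + 1))

    report_set = ReportSet(
        reports=reports, provenance=list(config.quarters), log=ParseLog()
    )
    truth = GroundTruth(frame=pd.DataFrame(truth_rows), config=config)
    return report_set, truth


def simulate_crude_cells(
    n_reports: int,
    drug_prevalence: float,
    event_background_rate: float,
    relative_risk: float,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw (a, b, c, d) crude cells for many replicates at once.

    Samples the cell counts directly from the generative model's binomial
    structure — distributionally identical to running
    :func:`generate_reports` and tabulating, since background drugs/terms
    and demographics are independent of the exposure and event indicators.
    Intended for Monte-Carlo calibration work (coverage, estimator
    consistency) where building millions of report objects would be waste.
    Returns an (n_replicates, 4) integer array.
    """
    p_event_exposed = min(1.0, event_background_rate * relative_risk)
    n_exposed = rng.binomial(n_reports, drug_prevalence, size=n_replicates)
    a = rng.binomial(n_exposed, p_event_exposed)
    c = rng.binomial(n_reports - n_exposed, event_background_rate)
    b = n_exposed - a
    d = n_reports - n_exposed - c
    return np.stack([a, b, c, d], axis=1)


def _age_fields(age_years: float | None) -> tuple[str, str]:
    if age_years is None:
        return "", ""
    return f"{age_years:.10g}", "YR"


_SEX_OUT = {"female": "F", "male": "M", "unspecified": ""}


def write_faers_ascii(reports: ReportSet, out_dir: Path | str) -> dict[str, dict[str, Path]]:
    """Emit per-quarter DEMO/DRUG/REAC files in the ingestion dialect.

    Dollar-delimited with a header line; sets are written in sorted order so
    identical ReportSets produce byte-identical files. Returns
    {quarter: {"DEMO": path, "DRUG": path, "REAC": path}}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    quarters = sorted(
        {r.quarter for r in reports} | set(reports.provenance)
    )
    by_quarter: dict[str, list[AdverseEventReport]] = {q: [] for q in quarters}
    for r in reports:
        by_quarter[r.quarter].append(r)

    paths: dict[str, dict[str, Path]] = {}
    for q in quarters:
        qreports = sorted(by_quarter[q], key=lambda r: (r.caseid, r.primaryid))
        demo_path = out_dir / f"DEMO{q}.txt"
        drug_path = out_dir / f"DRUG{q}.txt"
        reac_path = out_dir / f"REAC{q}.txt"
        with open(demo_path, "w", encoding="utf-8") as fh:
            fh.write("primaryid$caseid$age$age_cod$sex\n")
            for r in qreports:
                age, code = _age_fields(r.age_years)
                fh.write(f"{r.primaryid}${r.caseid}${age}${code}${_SEX_OUT[r.sex]}\n")
        with open(drug_path, "w", encoding="utf-8") as fh:
            fh.write("primaryid$caseid$drugname\n")
            for r in qreports:
                for name in sorted(r.drugs):
                    fh.write(f"{r.primaryid}${r.caseid}${name}\n")
        with open(reac_path, "w", encoding="utf-8") as fh:
            fh.write("primaryid$caseid$pt\n")
            for r in qreports:
                for pt in sorted(r.reactions):
                    fh.write(f"{r.primaryid}${r.caseid}${pt}\n")
        paths[q] = {"DEMO": demo_path, "DRUG": drug_path, "REAC": reac_path}
    return paths
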