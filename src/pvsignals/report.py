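"""End-to-end analysis pipeline with machine-readable table output.

``run_analysis`` drives parse → link → dedup → crude table → statistics →
stratified Mantel-Haenszel → quarterly trends → event ranking →
demographics over a directory of quarterly FAERS-style files, and writes
each result as a TSV (for human diffing) with a JSON sidecar (full
precision, for programmatic use), plus a run log and a manifest.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from ._util import round_half_up
from .contingency import (
    DrugQuery,
    EventQuery,
    NotEstimableError,
    build_table,
    mantel_haenszel_or,
    mantel_haenszel_rr,
    rank_events,
    strata_to_frame,
    stratify,
    age_bin_label,
    AGE_BIN_LABELS,
    UNSPECIFIED_AGE,
)
from .faers_io import ReportSet, load_quarters
from .signal_stats import DEFAULT_HYPERPARAMETERS, evaluate_signal
from .trends import quarterly_series


class PipelineError(RuntimeError):
    """A fatal failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs."""

    input_dir: Path
    quarters: Sequence[str]
    drug_names: Sequence[str] = ("TEDUGLUTIDE", "GATTEX")
    event_terms: Sequence[str] = ("Pancreatitis",)
    stratifications: Sequence[str] = ("sex", "age")
    top_k: int = 10
    output_dir: Path = Path("pvsignals_out")
    precision: int = 2

    def validate(self) -> None:
        if not list(self.quarters):
            raise PipelineError("config", "quarter range is empty")
        if not list(self.drug_names):
            raise PipelineError("config", "drug query is empty")
        if not list(self.event_terms):
            raise PipelineError("config", "event query is empty")
        if self.top_k < 1:
            raise PipelineError("config", "top_k must be >= 1")


@dataclass
class ReportBundle:
    """Paths and in-memory frames produced by one run."""

    paths: dict[str, Path]
    frames: dict[str, pd.DataFrame]
    reports: ReportSet


def summarize_demographics(reports: ReportSet, drug: DrugQuery) -> pd.DataFrame:
    """Age-bin and sex breakdown of the drug-exposed reports.

    Percentages are computed within the reports that provide the attribute;
    rows for unspecified values carry the count but no percentage.
    """
    exposed = [r for r in reports if drug.matches(r)]
    rows = []

    age_counts = {label: 0 for label in list(AGE_BIN_LABELS) + [UNSPECIFIED_AGE]}
    for r in exposed:
        age_counts[age_bin_label(r.age_years)] += 1
    known_age = sum(v for k, v in age_counts.items() if k != UNSPECIFIED_AGE)
    for label in AGE_BIN_LABELS:
        pct = 100.0 * age_counts[label] / known_age if known_age else None
        rows.append(("Age (in years)", label, age_counts[label], pct))
    rows.append(("Age (in years)", UNSPECIFIED_AGE, age_counts[UNSPECIFIED_AGE], None))

    sex_counts = {"Female": 0, "Male": 0, "Unspecified sex": 0}
    for r in exposed:
        key = {"female": "Female", "male": "Male"}.get(r.sex, "Unspecified sex")
        sex_counts[key] += 1
    known_sex = sex_counts["Female"] + sex_counts["Male"]
    for label in ("Female", "Male"):
        pct = 100.0 * sex_counts[label] / known_sex if known_sex else None
        rows.append(("Sex", label, sex_counts[label], pct))
    rows.append(("Sex", "Unspecified sex", sex_counts["Unspecified sex"], None))

    return pd.DataFrame(rows, columns=["characteristic", "category", "n", "pct"])


def _write_frame(frame: pd.DataFrame, path: Path, written: list[Path], precision: int) -> None:
    shown = frame.copy()
    for col in shown.columns:
        if shown[col].dtype.kind == "f":
            shown[col] = shown[col].map(
                lambda x: round_half_up(x, precision) if pd.notna(x) else x
            )
    shown.to_csv(path, sep="\t", index=False)
    written.append(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(frame.to_dict(orient="records"), indent=1, default=str))
    written.append(sidecar)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full pipeline; any fatal stage aborts and removes partial output."""
    config.validate()
    drug = DrugQuery(config.drug_names)
    event = EventQuery(config.event_terms)

    try:
        reports = load_quarters(config.input_dir, list(config.quarters))
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError("ingest", str(exc)) from exc

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    frames: dict[str, pd.DataFrame] = {}
    try:
        # crude table + statistics
        table = build_table(reports, drug, event)
        frames["contingency"] = table.to_frame(
            drug_label=str(config.drug_names[0]).strip().capitalize(),
            event_label=str(config.event_terms[0]).strip(),
        ).reset_index(names="group")
        stats = evaluate_signal(table, DEFAULT_HYPERPARAMETERS)
        frames["signals"] = stats.to_frame()

        # stratified + MH
        for axis in config.stratifications:
            strata = stratify(reports, drug, event, by=axis)
            frame = strata_to_frame(strata)
            try:
                frame.attrs["mh_ror"] = mantel_haenszel_or(strata)
            except NotEstimableError:
                frame.attrs["mh_ror"] = None
            try:
                frame.attrs["mh_prr"] = mantel_haenszel_rr(strata)
            except NotEstimableError:
                frame.attrs["mh_prr"] = None
            frame["mh_ror"] = frame.attrs["mh_ror"]
            frame["mh_prr"] = frame.attrs["mh_prr"]
            frames[f"strata_{axis}"] = frame

        # demographics, trends, ranking
        frames["demographics"] = summarize_demographics(reports, drug)
        frames["trends"] = quarterly_series(reports, drug, event).frame
        ranked = rank_events(reports, drug, config.top_k)
        frames["top_events"] = pd.DataFrame(
            [
                {
                    "pt": name,
                    "cases": count,
                    "ror": None if st.ror is None else st.ror.value,
                    "ror_lo": None if st.ror is None else st.ror.lo,
                    "ror_hi": None if st.ror is None else st.ror.hi,
                    "prr": None if st.prr is None else st.prr.value,
                    "prr_lo": None if st.prr is None else st.prr.lo,
                    "prr_hi": None if st.prr is None else st.prr.hi,
                }
                for name, count, st in ranked
            ]
        )

        paths: dict[str, Path] = {}
        for name, frame in frames.items():
            path = out / f"{name}.tsv"
            _write_frame(frame, path, written, config.precision)
            paths[name] = path

        log_path = out / "run_log.txt"
        log_lines = reports.log.lines() + [
            f"reports analysed: {len(reports)}",
            f"quarters: {', '.join(config.quarters)}",
        ]
        log_path.write_text("\n".join(log_lines) + "\n")
        written.append(log_path)
        paths["run_log"] = log_path

        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(
                {
                    "pvsignals_version": __version__,
                    "input_dir": str(config.input_dir),
                    "quarters": list(config.quarters),
                    "drug_names": list(config.drug_names),
                    "event_terms": list(config.event_terms),
                    "stratifications": list(config.stratifications),
                    "top_k": config.top_k,
                    "precision": config.precision,
                },
                indent=1,
            )
        )
        written.append(manifest_path)
        paths["manifest"] = manifest_path
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # noqa: BLE001
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("report", str(exc)) from exc

    return ReportBundle(paths=paths, frames=frames, reports=reports)
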