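"""File interfaces and the end-to-end pipeline.

Cohorts travel as two UTF-8 CSV files: a patient table
(``patient_id,surgery_year,cohort,age,gender,bmi,asa,charnley,deceased,
returned_pre,returned_m3,returned_m12``) and a long-format response table
(``patient_id,timepoint,instrument,item,score``) in which absent responses
are absent rows.  Reading is strict: malformed headers, unknown instrument
tokens, duplicate response keys, out-of-range scores, and responses at a
timepoint the patient did not return are hard errors naming the offending
row.  :func:`run_pipeline` drives simulate/load -> clinimetric selection ->
triage of both cohorts -> allocation comparison, and records a manifest of
digests, seeds, and decisions so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinimetrics import (
    SelectionConfig,
    SelectionResult,
    paper_profile,
    run_selection,
)
from .cohort_stats import response_rate
from .instruments import (
    ASA,
    Charnley,
    Cohort,
    CohortLabel,
    Instrument,
    PatientRecord,
    Timepoint,
    standard_items,
    validate_record,
)
from .synthetic_cohort import make_paperlike_fixture
from .triage_engine import compare_rates, load_rule, save_rule, triage_cohort

__all__ = [
    "CohortValidationError",
    "PipelineConfig",
    "RunManifest",
    "read_cohort",
    "write_cohort",
    "split_by_label",
    "run_pipeline",
    "load_pipeline_config",
]

_PATIENT_COLS = ["patient_id", "surgery_year", "cohort", "age", "gender",
                 "bmi", "asa", "charnley", "deceased", "returned_pre",
                 "returned_m3", "returned_m12"]
_RESPONSE_COLS = ["patient_id", "timepoint", "instrument", "item", "score"]
_BOOL = {"true": True, "false": False, "1": True, "0": False}


class CohortValidationError(ValueError):
    """Input data violate the cohort schema; carries located messages."""

    def __init__(self, messages: list[str]):
        self.messages = messages
        preview = "\n".join(messages[:20])
        more = f"\n... and {len(messages) - 20} more" if len(messages) > 20 else ""
        super().__init__(f"{len(messages)} validation error(s):\n{preview}{more}")


def _parse_bool(token: str, where: str) -> bool:
    try:
        return _BOOL[str(token).strip().lower()]
    except KeyError:
        raise CohortValidationError([f"{where}: invalid boolean {token!r}"])


def write_cohort(cohort: Cohort, patients_path: str | Path,
                 responses_path: str | Path) -> None:
    prows = []
    rrows = []
    for r in cohort.records:
        prows.append({
            "patient_id": r.patient_id, "surgery_year": r.surgery_year,
            "cohort": r.cohort_label.value, "age": r.age_years,
            "gender": r.gender, "bmi": r.bmi_kg_m2, "asa": r.asa.value,
            "charnley": r.charnley.value,
            "deceased": str(r.deceased).lower(),
            "returned_pre": str(r.has_returned(Timepoint.PRE)).lower(),
            "returned_m3": str(r.has_returned(Timepoint.M3)).lower(),
            "returned_m12": str(r.has_returned(Timepoint.M12)).lower(),
        })
        for (instrument, idx, t), score in sorted(
                r.responses.items(),
                key=lambda kv: (kv[0][2].value, kv[0][0].value, kv[0][1])):
            rrows.append({"patient_id": r.patient_id, "timepoint": t.value,
                          "instrument": instrument.value, "item": idx,
                          "score": score})
    pd.DataFrame(prows, columns=_PATIENT_COLS).to_csv(patients_path, index=False)
    pd.DataFrame(rrows, columns=_RESPONSE_COLS).to_csv(responses_path, index=False)


def read_cohort(patients_path: str | Path,
                responses_path: str | Path) -> Cohort:
    """Parse and validate the two cohort CSVs; raises on any violation."""
    try:
        patients = pd.read_csv(patients_path, dtype=str,
                               encoding="utf-8-sig").fillna("")
        responses = pd.read_csv(responses_path, dtype=str,
                                encoding="utf-8-sig").fillna("")
    except Exception as exc:
        raise CohortValidationError([f"malformed CSV: {exc}"]) from exc
    errors: list[str] = []
    if list(patients.columns) != _PATIENT_COLS:
        raise CohortValidationError(
            [f"{patients_path}: header must be {','.join(_PATIENT_COLS)}"])
    if list(responses.columns) != _RESPONSE_COLS:
        raise CohortValidationError(
            [f"{responses_path}: header must be {','.join(_RESPONSE_COLS)}"])

    records: dict[str, PatientRecord] = {}
    for i, row in patients.iterrows():
        where = f"{patients_path}:{i + 2}"
        pid = row["patient_id"]
        if pid in records:
            errors.append(f"{where}: duplicate patient_id {pid!r}")
            continue
        try:
            rec = PatientRecord(
                patient_id=pid,
                surgery_year=int(row["surgery_year"]),
                cohort_label=CohortLabel(row["cohort"]),
                age_years=float(row["age"]),
                gender=row["gender"],
                bmi_kg_m2=float(row["bmi"]),
                asa=ASA(row["asa"]),
                charnley=Charnley(row["charnley"]),
                deceased=_parse_bool(row["deceased"], where),
                returned={
                    Timepoint.PRE: _parse_bool(row["returned_pre"], where),
                    Timepoint.M3: _parse_bool(row["returned_m3"], where),
                    Timepoint.M12: _parse_bool(row["returned_m12"], where),
                },
            )
        except CohortValidationError as exc:
            errors.extend(exc.messages)
            continue
        except (ValueError, KeyError) as exc:
            errors.append(f"{where}: {exc}")
            continue
        records[pid] = rec

    seen: set[tuple] = set()
    for i, row in responses.iterrows():
        where = f"{responses_path}:{i + 2}"
        pid = row["patient_id"]
        rec = records.get(pid)
        if rec is None:
            errors.append(f"{where}: unknown patient_id {pid!r}")
            continue
        try:
            instrument = Instrument(row["instrument"])
            t = Timepoint(row["timepoint"])
            idx = int(row["item"])
            score = int(row["score"])
        except (ValueError, KeyError) as exc:
            errors.append(f"{where}: {exc}")
            continue
        key = (pid, instrument, idx, t)
        if key in seen:
            errors.append(f"{where}: duplicate response for {pid} "
                          f"{instrument.value} #{idx} at {t.value}")
            continue
        seen.add(key)
        rec.responses[(instrument, idx, t)] = score
    if errors:
        raise CohortValidationError(errors)

    defs = standard_items()
    for rec in records.values():
        for v in validate_record(rec, defs):
            errors.append(f"{rec.patient_id}: {v.rule}: {v.message}")
    if errors:
        raise CohortValidationError(errors)
    labels = {r.cohort_label for r in records.values()}
    label = labels.pop() if len(labels) == 1 else None
    return Cohort(label, list(records.values()), n_thas=len(records))


def split_by_label(cohort: Cohort) -> dict[CohortLabel, Cohort]:
    out: dict[CohortLabel, Cohort] = {}
    for label in CohortLabel:
        recs = [r for r in cohort.records if r.cohort_label is label]
        if recs:
            out[label] = Cohort(label, recs, n_thas=len(recs))
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration (strict: unknown keys are errors)


@dataclass(frozen=True)
class PipelineConfig:
    profile: str = "paper"  # "stated" | "paper"
    rule: str = "candidate_9item"
    timepoint: str = "M3"
    patients: str | None = None  # load these CSVs ...
    responses: str | None = None
    simulate: bool = True  # ... or simulate the two-cohort fixture

    def selection_config(self) -> SelectionConfig:
        if self.profile == "paper":
            return paper_profile()
        if self.profile == "stated":
            return SelectionConfig()
        raise ValueError(f"unknown profile {self.profile!r}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**payload)


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    input_digests: dict[str, str]
    stage_seconds: dict[str, float]
    decisions_log: list[str]
    outputs: list[str]
    summary: dict = field(default_factory=dict)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, seed: int,
                 outdir: str | Path) -> RunManifest:
    """Simulate or load, select items, triage both cohorts, compare rates.

    Every artifact lands under ``outdir``; the manifest records input
    digests, the seed, per-stage wall times, and the machine-parseable
    selection log.  All artifacts except the manifest (whose timings vary)
    are byte-identical across reruns with the same inputs and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(__version__, seed, cfg_hash, {}, {}, [], [])
    timers: dict[str, float] = {}

    def stage(name):
        timers[name] = time.perf_counter()

    def done(name):
        manifest.stage_seconds[name] = round(time.perf_counter() - timers[name], 3)

    stage("load")
    if config.simulate:
        training, test = make_paperlike_fixture(seed)
        for coh, tag in ((training, "training"), (test, "test")):
            ppath = outdir / f"patients_{tag}.csv"
            rpath = outdir / f"responses_{tag}.csv"
            write_cohort(coh, ppath, rpath)
            manifest.outputs += [str(ppath), str(rpath)]
            manifest.input_digests[ppath.name] = _digest(ppath)
            manifest.input_digests[rpath.name] = _digest(rpath)
    else:
        if not config.patients or not config.responses:
            raise ValueError("patients and responses paths required when "
                             "simulate is false")
        manifest.input_digests["patients"] = _digest(Path(config.patients))
        manifest.input_digests["responses"] = _digest(Path(config.responses))
        both = read_cohort(config.patients, config.responses)
        parts = split_by_label(both)
        if (CohortLabel.TRAINING not in parts or CohortLabel.TEST not in parts):
            raise ValueError("input must contain TRAINING and TEST patients")
        training, test = parts[CohortLabel.TRAINING], parts[CohortLabel.TEST]
    done("load")

    stage("selection")
    candidate = load_rule(config.rule)
    selection: SelectionResult = run_selection(training, candidate,
                                               config.selection_config())
    manifest.decisions_log = list(selection.log)
    rule_path = outdir / "final_rule.json"
    save_rule(selection.final_rule, rule_path)
    decisions_path = outdir / "selection_decisions.csv"
    pd.DataFrame([
        {"item": d.item_id, "status": d.status,
         "reasons": ";".join(r.value for r in d.reasons)}
        for d in selection.decisions
    ]).to_csv(decisions_path, index=False)
    manifest.outputs += [str(rule_path), str(decisions_path)]
    done("selection")

    stage("triage")
    t = Timepoint(config.timepoint)
    summaries = {}
    for coh, tag in ((training, "training"), (test, "test")):
        summary, outcomes = triage_cohort(coh, selection.final_rule, t)
        summaries[tag] = summary
        alloc_path = outdir / f"allocations_{tag}.csv"
        pd.DataFrame([
            {"patient_id": o.patient_id, "allocation": o.allocation.value,
             "triggered": ";".join(c.item.item_id for c in o.triggered),
             "missing": ";".join(d.item_id for d in o.missing_items)}
            for o in outcomes
        ]).to_csv(alloc_path, index=False)
        manifest.outputs.append(str(alloc_path))
    done("triage")

    stage("compare")
    comparison = compare_rates(summaries["training"], summaries["test"])
    comp_path = outdir / "comparison.json"
    comp_payload = {
        "table": comparison.table.astype(int).tolist(),
        "method": comparison.method,
        "p_value": comparison.p_value,
        "chi2_uncorrected": comparison.statistic_uncorrected,
        "p_uncorrected": comparison.p_uncorrected,
        "chi2_corrected": comparison.statistic_corrected,
        "p_corrected": comparison.p_corrected,
    }
    comp_path.write_text(json.dumps(comp_payload, indent=2) + "\n",
                         encoding="utf-8")
    manifest.outputs.append(str(comp_path))
    done("compare")

    manifest.summary = {
        "n_training": len(training), "n_test": len(test),
        "removed": sorted(selection.removed),
        "retained": selection.retained,
        "response_rate_m3_training": response_rate(
            training.n_returned(t), training.n_thas,
            training.n_deceased).percent,
        "hospital_percent_training": summaries["training"].hospital_percent,
        "hospital_percent_test": summaries["test"].hospital_percent,
        "p_value": comparison.p_value,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(asdict(manifest), indent=2, default=str) + "\n",
        encoding="utf-8")
    return manifest
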