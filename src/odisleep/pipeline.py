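"""File-based pipeline stages and the end-to-end orchestrator.

Stages communicate through headed CSV files so every intermediate is
inspectable and the whole run is reproducible from one config and one
seed: simulate -> preprocess -> odi -> classify -> evaluate. A manifest
records per-stage row counts and the seeds used.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import (
    SVMSpec,
    cutoff_predict,
    optimize_cutoff,
    svm_crossval,
    svm_multiclass,
)
from .evaluation import (
    ConfusionMatrix,
    chi_square_test,
    confusion_metrics,
    roc_auc,
)
from .odi import compute_odi
from .preprocessing import ExclusionRules, apply_exclusions, remove_artifacts
from .reference import (
    CONFUSION_4CLASS,
    GENDER_SEVERITY_COUNTS,
    GROUP_SUMMARIES,
    TST_SEVERITY_COUNTS,
)
from .scoring import SEVERITIES, binary_labels
from .synthetic import (
    CohortSpec,
    OximeterModel,
    PatientRecord,
    cohort_frame,
    events_frame,
    generate_cohort,
    plant_events,
    synthesize_trace,
)
from .trace import SpO2Trace

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]

# distinct sub-streams per patient, derived from the per-patient seed
_EVENT_SEED_OFFSET = 500_009
_TRACE_SEED_OFFSET = 900_001


class PipelineConfig:
    """Validated pipeline configuration (a thin wrapper over a mapping)."""

    def __init__(self, raw: Mapping[str, Any]):
        if "seed" not in raw:
            raise ValueError("config must set an explicit 'seed' (no silent nondeterminism)")
        self.seed = int(raw["seed"])
        cohort = dict(raw.get("cohort", {}))
        cohort.setdefault("seed", self.seed)
        if "severity_mix" in cohort:
            cohort["severity_mix"] = tuple(cohort["severity_mix"])
        self.cohort_spec = CohortSpec(**cohort)
        self.cohort_spec.validate()
        oxi = dict(raw.get("oximeter", {}))
        if "rate_thresholds" in oxi:
            oxi["rate_thresholds"] = tuple(oxi["rate_thresholds"])
        self.oximeter = OximeterModel(**oxi)
        self.oximeter.validate()
        self.odi_kwargs = dict(raw.get("odi", {}))
        svm = dict(raw.get("svm", {}))
        svm.setdefault("seed", self.seed)
        for key in ("features", "C_grid", "gamma_grid"):
            if key in svm:
                svm[key] = tuple(svm[key])
        self.svm_spec = SVMSpec(**svm)
        self.tasks: list[str] = list(raw.get("tasks", ["severe", "mod_severe"]))
        for task in self.tasks:
            if task not in ("severe", "mod_severe", "fourclass"):
                raise ValueError(f"unknown task {task!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _trace_path(traces_dir: Path, patient_id: str) -> Path:
    return traces_dir / f"{patient_id}.csv"


def simulate_stage(config: PipelineConfig, out_dir: Path) -> dict[str, int]:
    """Generate cohort table, respiratory event lists, and SpO2 traces."""
    out_dir.mkdir(parents=True, exist_ok=True)
    traces_dir = out_dir / "traces"
    traces_dir.mkdir(exist_ok=True)
    records = generate_cohort(config.cohort_spec)
    cohort_frame(records).to_csv(out_dir / "cohort.csv", index=False)
    all_events = []
    for rec in records:
        events = plant_events(rec.ahi, rec.tst_hours, rec.seed + _EVENT_SEED_OFFSET)
        all_events.append(events_frame(events, rec.patient_id))
        trace = synthesize_trace(
            events,
            int(round(rec.tst_min * 60)),
            config.oximeter,
            rec.seed + _TRACE_SEED_OFFSET,
        )
        trace.to_csv(_trace_path(traces_dir, rec.patient_id))
    ev = pd.concat(all_events, ignore_index=True) if all_events else pd.DataFrame()
    ev.to_csv(out_dir / "events.csv", index=False)
    return {"cohort_rows": len(records), "event_rows": len(ev)}


def preprocess_stage(traces_dir: Path, cohort_csv: Path, out_dir: Path) -> dict[str, int]:
    """Mask artifacts in every trace and apply the cohort exclusion cascade."""
    out_dir.mkdir(parents=True, exist_ok=True)
    clean_dir = out_dir / "traces"
    clean_dir.mkdir(exist_ok=True)
    cohort = pd.read_csv(cohort_csv)
    records = [PatientRecord(**row) for row in cohort.to_dict("records")]
    kept, excluded = apply_exclusions(records, ExclusionRules())
    for rec in kept:
        trace = SpO2Trace.from_csv(_trace_path(traces_dir, rec.patient_id))
        remove_artifacts(trace).to_csv(_trace_path(clean_dir, rec.patient_id))
    kept_df = cohort_frame(kept)
    kept_df["tst_ge_4h"] = [r.tst_ge_4h for r in kept]
    kept_df.to_csv(out_dir / "cohort_kept.csv", index=False)
    pd.DataFrame(
        {"patient_id": [e.record.patient_id for e in excluded],
         "reason": [e.reason for e in excluded]}
    ).to_csv(out_dir / "exclusions.csv", index=False)
    return {"kept_rows": len(kept), "excluded_rows": len(excluded)}


def odi_stage(traces_dir: Path, out_csv: Path, **odi_kwargs) -> dict[str, int]:
    """Compute the four desaturation indices for every preprocessed trace."""
    rows = []
    for path in sorted(traces_dir.glob("*.csv")):
        trace = SpO2Trace.from_csv(path)
        result = compute_odi(trace, **odi_kwargs)
        row = {"patient_id": path.stem, **result.as_dict()}
        row.update({f"n_events_{k}": v for k, v in result.counts().items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return {"odi_rows": len(df)}


def classify_stage(
    features_csv: Path,
    cohort_csv: Path,
    task: str,
    out_csv: Path,
    *,
    model: str = "svm",
    svm_spec: SVMSpec | None = None,
) -> dict[str, int]:
    """Fit/evaluate one task on the computed features and write predictions."""
    feats = pd.read_csv(features_csv).set_index("patient_id")
    cohort = pd.read_csv(cohort_csv).set_index("patient_id")
    merged = feats.join(cohort[["severity", "nc", "bmi", "ess"]], how="inner")
    if task == "fourclass":
        labels: Sequence = merged["severity"].tolist()
    else:
        labels = binary_labels(merged["severity"].tolist(), task)
    spec = svm_spec or SVMSpec()
    if model == "svm":
        if task == "fourclass":
            preds = svm_multiclass(merged, labels, spec)
        else:
            preds = svm_crossval(merged, labels, spec, task=task)
        frame = preds.frame
    elif model == "cutoff":
        feature = spec.features[0] if len(spec.features) == 1 else "odi4a"
        result = optimize_cutoff(merged[feature], labels, feature=feature, task=task)
        frame = cutoff_predict(merged[feature], labels, result.rule).frame
    else:
        raise ValueError(f"unknown model {model!r}")
    frame.to_csv(out_csv, index=False)
    return {"prediction_rows": len(frame)}


def evaluate_stage(prediction_csvs: Mapping[str, Path], out_json: Path) -> dict:
    """Summarise every task's predictions into one machine-readable report."""
    report: dict[str, Any] = {}
    for task, path in prediction_csvs.items():
        frame = pd.read_csv(path)
        if task == "fourclass":
            labels: tuple = SEVERITIES
        else:
            labels = (0, 1)
        cm = ConfusionMatrix.from_predictions(
            type("P", (), {"frame": frame})(), labels
        )
        metrics = confusion_metrics(cm)
        block = {
            "confusion": cm.counts.tolist(),
            "labels": list(cm.labels),
            "overall_accuracy_pct": metrics.overall_accuracy_pct,
            "sensitivity_pct": metrics.sensitivity_pct,
        }
        if task != "fourclass":
            block["specificity_pct"] = metrics.specificity_pct
            if frame["score"].nunique() > 1:
                block["auc"] = roc_auc(frame["score"], frame["true"]).auc
        report[task] = block
    out_json.parent.mkdir(parents=True, exist_ok=True)
    with open(out_json, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages in order; returns the evaluation report."""
    out_dir = Path(out_dir)
    manifest: dict[str, Any] = {"version": __version__, "seed": config.seed, "stages": {}}
    try:
        manifest["stages"]["simulate"] = simulate_stage(config, out_dir / "sim")
        manifest["stages"]["preprocess"] = preprocess_stage(
            out_dir / "sim" / "traces", out_dir / "sim" / "cohort.csv", out_dir / "prep"
        )
        manifest["stages"]["odi"] = odi_stage(
            out_dir / "prep" / "traces", out_dir / "odi.csv", **config.odi_kwargs
        )
        predictions = {}
        for task in config.tasks:
            out_csv = out_dir / f"predictions_{task}.csv"
            manifest["stages"][f"classify_{task}"] = classify_stage(
                out_dir / "odi.csv",
                out_dir / "prep" / "cohort_kept.csv",
                task,
                out_csv,
                svm_spec=config.svm_spec,
            )
            predictions[task] = out_csv
        report = evaluate_stage(predictions, out_dir / "report.json")
    except Exception as exc:  # annotate with the failing stage
        done = list(manifest["stages"])
        stage = "unknown" if not done else f"after {done[-1]}"
        raise RuntimeError(f"pipeline aborted ({stage}): {exc}") from exc
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def make_fixtures(out_dir: str | Path) -> None:
    """Write the small worked-example inputs used by the test suite."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, cm in CONFUSION_4CLASS.items():
        pd.DataFrame(cm.counts, index=cm.labels, columns=cm.labels).to_csv(
            out_dir / f"confusion_{name}.csv"
        )
    pd.DataFrame(
        GENDER_SEVERITY_COUNTS, index=["female", "male"], columns=SEVERITIES
    ).to_csv(out_dir / "gender_severity.csv")
    pd.DataFrame(
        TST_SEVERITY_COUNTS, index=["tst_lt_4h", "tst_ge_4h"], columns=SEVERITIES
    ).to_csv(out_dir / "tst_severity.csv")
    rows = []
    for var, groups in GROUP_SUMMARIES.items():
        for g in groups:
            rows.append({"variable": var, "group": g.label, "n": g.n,
                         "mean": g.mean, "sd": g.sd})
    pd.DataFrame(rows).to_csv(out_dir / "group_summaries.csv", index=False)

    quiet = OximeterModel(noise_sd=0.0, artifact_spike_rate=0.0, dropout_rate=0.0)
    flat = synthesize_trace([], 600, quiet, seed=0, resting_pct=96.0)
    flat.to_csv(out_dir / "trace_flat.csv")
    from .synthetic import PlantedEvent

    single = synthesize_trace(
        [PlantedEvent(onset_s=200, duration_s=20, depth_pct=6.0, kind="apnea")],
        600, quiet, seed=0, resting_pct=96.0,
    )
    single.to_csv(out_dir / "trace_single_event.csv")
    # artifact-laden trace with a known invalid-sample count: three
    # single-sample spikes (each invalidates itself and its recovery
    # sample) and one 5-s dropout -> 3*2 + 5 = 11 invalid samples
    x = np.full(600, 96.0)
    x[[100, 200, 300]] = 88.0
    x[400:405] = 40.0
    SpO2Trace(spo2=x).to_csv(out_dir / "trace_artifacts.csv")
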