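"""End-to-end run orchestration with content-addressed stage caching.

``run_pipeline`` executes phantom generation, then the cross-validated
strategy comparison (VOI extraction, augmentation, per-fold WGAN training,
pretraining, fine-tuning, prediction all happen inside the evaluation
harness). Each stage's outputs land in a directory named by a hash of every
input that determines them (stage config + seeds + upstream stage key), so a
rerun with the same config reuses completed stages and any config change
invalidates exactly the stages it reaches.

Events are appended to ``log.jsonl`` (one JSON object per line) and the run
manifest (full config echo, stage keys, cache hits, outputs) is written to
``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from .config import RunConfig
from .evaluation import classification_metrics, compare_strategies, roc_auc
from .phantom import PhantomCase, generate_cohort
from .volume_io import read_annotations, read_volume, write_annotations, write_volume


def _stage_key(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Log:
    def __init__(self, path: Path):
        self.path = path

    def emit(self, **event):
        event.setdefault("time", round(time.time(), 3))
        with open(self.path, "a") as fh:
            fh.write(json.dumps(event) + "\n")


def _phantom_stage(config: RunConfig, out: Path, log: _Log):
    n_b, n_m = config.cohort_sizes()
    key = _stage_key(
        {"stage": "phantom", "config": config.echo()["phantom"], "n": [n_b, n_m], "seed": config.master_seed}
    )
    stage_dir = out / f"phantom-{key}"
    manifest_csv = stage_dir / "manifest.csv"
    if (stage_dir / "done.json").exists():
        log.emit(stage="phantom", event="cache_hit", key=key)
        anns = read_annotations(manifest_csv)
        cases = [
            PhantomCase(read_volume(stage_dir / f"{a.case_id}.raw"), a, a.seed or 0) for a in anns
        ]
        return cases, key, stage_dir
    stage_dir.mkdir(parents=True, exist_ok=True)
    log.emit(stage="phantom", event="start", key=key, n_benign=n_b, n_malignant=n_m)
    cases = generate_cohort(n_b, n_m, config.phantom_config(), seed=config.master_seed)
    for case in cases:
        write_volume(case.volume, stage_dir / f"{case.annotation.case_id}.raw")
    write_annotations([c.annotation for c in cases], manifest_csv)
    (stage_dir / "done.json").write_text(json.dumps({"key": key, "n_cases": len(cases)}))
    log.emit(stage="phantom", event="done", key=key, n_cases=len(cases))
    return cases, key, stage_dir


def _evaluation_stage(config: RunConfig, cases, phantom_key: str, out: Path, log: _Log):
    key = _stage_key(
        {"stage": "evaluation", "config": config.echo(), "phantom_key": phantom_key}
    )
    stage_dir = out / f"evaluation-{key}"
    if (stage_dir / "done.json").exists():
        log.emit(stage="evaluation", event="cache_hit", key=key)
        return key, stage_dir
    stage_dir.mkdir(parents=True, exist_ok=True)
    log.emit(stage="evaluation", event="start", key=key)
    table, per_strategy = compare_strategies(cases, config.strategies(), config.cv_params())
    table.to_csv(stage_dir / "comparison.csv", index=False)
    metrics = {}
    for name, results in per_strategy.items():
        roc = roc_auc(results)
        metrics[name] = {**classification_metrics(results), "auc": roc.auc}
        import pandas as pd

        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}).to_csv(
            stage_dir / f"roc_{name}.csv", index=False
        )
        pd.DataFrame(
            [
                {"case_id": r.case_id, "true_label": r.true_label, "p_malignant": r.probability,
                 "predicted": r.predicted_label}
                for r in results
            ]
        ).to_csv(stage_dir / f"cases_{name}.csv", index=False)
    (stage_dir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    (stage_dir / "done.json").write_text(json.dumps({"key": key}))
    log.emit(stage="evaluation", event="done", key=key)
    return key, stage_dir


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "log.jsonl")
    log.emit(stage="run", event="start", preset=config.preset, master_seed=config.master_seed)

    cases, phantom_key, phantom_dir = _phantom_stage(config, out, log)
    eval_key, eval_dir = _evaluation_stage(config, cases, phantom_key, out, log)

    manifest = {
        "config": config.echo(),
        "stages": {
            "phantom": {"key": phantom_key, "dir": phantom_dir.name},
            "evaluation": {"key": eval_key, "dir": eval_dir.name},
        },
        "outputs": {
            "comparison": str(eval_dir / "comparison.csv"),
            "metrics": str(eval_dir / "metrics.json"),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.emit(stage="run", event="done")
    return manifest
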