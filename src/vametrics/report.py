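"""Machine-readable metric reports.

A report bundles everything a validation study should publish for one
dataset: the full N x N classification table (the transparency backbone
— readers can recompute any metric from it), per-cause sensitivity,
specificity and CCC, the overall block (kappa, overall CCC with the
weights actually used, PCCC by k, CSMF accuracy), and metadata tracing
every number back to the configuration that produced it.  Undefined
metrics appear as JSON null, never as 0.
"""

from __future__ import annotations

import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .core import ValidationDataset, build_confusion, csmf_of_predicted, csmf_of_true
from .csmf import csmf_accuracy, csmf_error_sets, total_absolute_error
from .individual import (
    UndefinedMetricError,
    ccc_weights,
    cohen_kappa,
    overall_ccc,
    pccc,
    per_cause_metrics,
)


def _clean(value):
    """NaN -> None recursively, so reports serialize as strict JSON."""
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, dict):
        return {k: _clean(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_clean(v) for v in value]
    return value


def build_report(
    dataset: ValidationDataset,
    ks: Sequence[int] = (),
    weights="equal",
    pc_convention: str = "rank",
    seed: int | None = None,
    extra_metadata: dict | None = None,
) -> dict:
    """Full metric report for one validation dataset."""
    conf = build_confusion(dataset)
    true = csmf_of_true(dataset)
    pred = csmf_of_predicted(dataset)
    per_cause = per_cause_metrics(conf)
    errors = csmf_error_sets(true, pred)

    pccc_block = {}
    for k in ks:
        pccc_block[str(k)] = pccc(dataset, k, convention=pc_convention)

    per_cause_block = {}
    n_undefined = 0
    for m, e in zip(per_cause, errors):
        vals = {
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "chance_corrected_concordance": m.ccc,
            "true_csmf": true[m.cause],
            "predicted_csmf": pred[m.cause],
            "absolute_csmf_error": e.absolute_error,
            "relative_csmf_error": e.relative_error,
        }
        n_undefined += sum(
            1 for v in vals.values() if isinstance(v, float) and math.isnan(v)
        )
        per_cause_block[m.cause] = vals

    report = {
        "metadata": {
            "tool": "vametrics",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "seed": seed,
            "weights_scheme": weights if isinstance(weights, str) else list(weights),
            "pc_convention": pc_convention,
            "n_records": len(dataset.records),
            "n_undefined_metrics": n_undefined,
            **(extra_metadata or {}),
        },
        "causes": list(dataset.causes.labels),
        "confusion_matrix": {
            "rows": "true cause",
            "columns": "predicted cause",
            "labels": list(dataset.causes.labels),
            "counts": conf.counts.tolist(),
        },
        "per_cause": per_cause_block,
        "overall": {
            "kappa": cohen_kappa(conf),
            "overall_ccc": overall_ccc(conf, weights=weights),
            "weights_used": ccc_weights(conf, weights),
            "pccc_by_k": pccc_block,
            "total_absolute_csmf_error": total_absolute_error(true, pred),
            "csmf_accuracy": csmf_accuracy(true, pred),
        },
    }
    return _clean(report)


def write_report(report: dict, path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, allow_nan=False) + "\n", encoding="utf-8"
    )


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
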