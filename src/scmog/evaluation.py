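"""Benchmark metrics for generated omics.

Generated ATAC is scored by AUROC against the binarized measurement (the
probability a random accessible entry outranks a random inaccessible one);
generated RNA by Pearson correlation on log-scaled expression (ln(1+x) on
both sides); generated protein by plain Pearson on the CLR scale.  The
headline numbers flatten the whole cells x features matrix; per-cell
distributions are available as a supplement since a global and a per-cell
average answer different questions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from scmog.generation import generate


@dataclass
class EvalReport:
    direction: str
    metric: str
    value: float
    n_cells: int
    n_features: int
    per_cell: list[float] | None = None
    config_hash: str = ""

    def __post_init__(self) -> None:
        if self.metric == "auroc" and not 0.0 <= self.value <= 1.0:
            raise ValueError("AUROC must lie in [0, 1]")
        if self.metric.startswith("pearson") and not -1.0 <= self.value <= 1.0:
            raise ValueError("Pearson correlation must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "metric": self.metric,
            "value": self.value,
            "n_cells": self.n_cells,
            "n_features": self.n_features,
            "per_cell": self.per_cell,
            "config_hash": self.config_hash,
        }


def _flat(a) -> np.ndarray:
    if sp.issparse(a):
        a = np.asarray(a.todense())
    return np.asarray(a, dtype=float).ravel()


def auroc(scores, truth) -> float:
    """Rank-based AUROC over all entries, midrank tie handling."""
    s, t = _flat(scores), _flat(truth)
    classes = np.unique(t)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("truth must be binary 0/1")
    if classes.size < 2:
        raise ValueError("AUROC undefined: truth contains a single class")
    return float(roc_auc_score(t, s))


def pearson(a, b) -> float:
    """Plain Pearson correlation over flattened entries."""
    x, y = _flat(a), _flat(b)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 entries")
    if np.std(x) == 0:
        raise ValueError("zero variance in the first argument")
    if np.std(y) == 0:
        raise ValueError("zero variance in the second argument")
    return float(np.corrcoef(x, y)[0, 1])


def pearson_log(generated_expression, measured_counts) -> float:
    """Pearson correlation between ln(1+generated) and ln(1+measured)."""
    return pearson(np.log1p(_flat(generated_expression)), np.log1p(_flat(measured_counts)))


def per_cell_metric(generated, measured, metric: str) -> list[float]:
    """Per-cell AUROC or log-Pearson; cells where the metric is undefined
    (single truth class, zero variance) are skipped."""
    g = np.asarray(generated, dtype=float)
    m = measured
    if sp.issparse(m):
        m = np.asarray(m.todense())
    m = np.asarray(m, dtype=float)
    out = []
    for i in range(g.shape[0]):
        try:
            if metric == "auroc":
                out.append(auroc(g[i], m[i]))
            elif metric == "pearson_log":
                out.append(pearson_log(g[i], m[i]))
            else:
                out.append(pearson(g[i], m[i]))
        except ValueError:
            continue
    return out


def benchmark_report(
    model,
    source_processed,
    target_reference,
    split=None,
    partition: str = "test",
    per_cell: bool = False,
) -> EvalReport:
    """Generate from ``source_processed`` and score against the reference.

    ``target_reference`` holds the measured target on the metric's natural
    scale: binarized peaks for rna2atac, (size-normalised) counts for
    atac2rna, CLR values for rna2adt.  When a split is given only the stated
    partition's cells are scored, so train cells cannot inflate the numbers.
    """
    src_values = source_processed.values
    tgt_values = target_reference.values if hasattr(target_reference, "values") else target_reference
    cell_ids = list(source_processed.cell_ids)
    if split is not None:
        idx = split.indices(partition)
        src_values = src_values[idx]
        tgt_values = tgt_values[idx]
        cell_ids = [cell_ids[i] for i in idx]

    view = SimpleNamespace(
        values=src_values,
        feature_ids=source_processed.feature_ids,
        cell_ids=cell_ids,
    )
    gen = generate(model, view)
    if sp.issparse(tgt_values):
        tgt_values = np.asarray(tgt_values.todense())
    tgt_values = np.asarray(tgt_values, dtype=float)

    if model.direction == "rna2atac":
        metric, value = "auroc", auroc(gen.values, tgt_values)
    elif model.direction == "atac2rna":
        metric, value = "pearson_log", pearson_log(gen.values, tgt_values)
    else:
        metric, value = "pearson", pearson(gen.values, tgt_values)

    cfg = {
        "direction": model.direction,
        "partition": partition if split is not None else "all",
        "n_cells": int(gen.values.shape[0]),
    }
    report = EvalReport(
        direction=model.direction,
        metric=metric,
        value=value,
        n_cells=int(gen.values.shape[0]),
        n_features=int(gen.values.shape[1]),
        per_cell=per_cell_metric(gen.values, tgt_values, metric) if per_cell else None,
        config_hash=hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12],
    )
    return report
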