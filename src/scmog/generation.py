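"""Apply a trained translator to new cells and QC the generated ATAC.

Generation is a pure function of (model, input): source features are aligned
to the model's training feature list by id (missing features zero-filled,
extras dropped), the encoder/decoder pair is applied, and the output is
returned on the natural scale of the target modality — peak probabilities
for rna2atac, the negative-binomial mean as the expression estimate for
atac2rna, CLR-scale abundances for rna2adt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from scmog.networks import TranslatorModel
from scmog.preprocessing import EmptyAfterQCError, QCReport

logger = logging.getLogger(__name__)


@dataclass
class GeneratedMatrix:
    """Output of a translator over a set of cells.

    ``kind`` records the value scale: atac probabilities, binary peaks,
    nb_mean expression, or clr protein abundances.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str
    kind: str  # probabilities | binary | nb_mean | clr
    source_model: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.modality == "atac":
            if self.kind == "probabilities" and (
                (self.values < 0).any() or (self.values > 1).any()
            ):
                raise ValueError("ATAC probabilities must lie in [0, 1]")
            if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binarized ATAC must be 0/1")
        if self.kind == "nb_mean" and (self.values <= 0).any():
            raise ValueError("NB means must be strictly positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def align_features(
    values, feature_ids: list[str], model_features: list[str]
) -> tuple[np.ndarray, int, int]:
    """Reorder columns to the model's training features.

    Features the model knows but the input lacks become zero columns; input
    features the model never saw are dropped.  Returns (aligned matrix,
    n_matched, n_dropped).  Refuses to proceed when fewer than half of the
    model's features are present — generating from a mostly-zero input would
    be silently meaningless.
    """
    if sp.issparse(values):
        values = np.asarray(values.todense())
    values = np.asarray(values, dtype=float)
    pos = {f: j for j, f in enumerate(feature_ids)}
    matched = [f for f in model_features if f in pos]
    if len(matched) < 0.5 * len(model_features):
        raise ValueError(
            f"only {len(matched)}/{len(model_features)} model features present in "
            "the input (< 50%); refusing to generate"
        )
    out = np.zeros((values.shape[0], len(model_features)))
    for j, f in enumerate(model_features):
        if f in pos:
            out[:, j] = values[:, pos[f]]
    n_dropped = len(feature_ids) - len(matched)
    if len(matched) < len(model_features) or n_dropped:
        logger.info(
            "feature alignment: %d matched, %d zero-filled, %d dropped",
            len(matched), len(model_features) - len(matched), n_dropped,
        )
    return out, len(matched), n_dropped


def generate(
    model: TranslatorModel,
    source,
    batch_size: int = 512,
    log_scale: bool = False,
    sample_counts: bool = False,
    rng: np.random.Generator | None = None,
) -> GeneratedMatrix:
    """Translate processed source cells into the target modality.

    ``source`` is a ProcessedMatrix (preprocessed with the model's stored
    stats).  For atac2rna the default output is the NB mean; pass
    ``log_scale=True`` for log1p of the mean, or ``sample_counts=True`` to
    draw integer counts from the fitted NB (needs ``rng``).
    """
    x, _, _ = align_features(source.values, source.feature_ids, model.source_features)
    outs = []
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        out = model.forward(xb)
        if model.direction == "atac2rna":
            mu, theta = out
            if sample_counts:
                if rng is None:
                    raise ValueError("sample_counts=True requires rng")
                lam = rng.gamma(shape=theta, scale=mu / theta)
                out = rng.poisson(lam).astype(float)
            else:
                out = mu
        outs.append(out)
    values = np.vstack(outs)
    if model.direction == "rna2atac":
        kind, modality = "probabilities", "atac"
    elif model.direction == "atac2rna":
        kind, modality = ("counts" if sample_counts else "nb_mean"), "rna"
        if log_scale and not sample_counts:
            values = np.log1p(values)
            kind = "log1p_nb_mean"
    else:
        kind, modality = "clr", "adt"
    return GeneratedMatrix(
        values=values,
        cell_ids=list(source.cell_ids),
        feature_ids=list(model.target_features),
        modality=modality,
        kind=kind,
        source_model=model.direction,
    )


def binarize_predictions(g: GeneratedMatrix, threshold: float = 0.1) -> GeneratedMatrix:
    """Peak probabilities to calls: value >= threshold becomes 1 (inclusive
    boundary)."""
    if g.modality != "atac" or g.kind != "probabilities":
        raise ValueError("binarize_predictions expects ATAC probabilities")
    return GeneratedMatrix(
        values=(g.values >= threshold).astype(float),
        cell_ids=list(g.cell_ids),
        feature_ids=list(g.feature_ids),
        modality="atac",
        kind="binary",
        source_model=g.source_model,
        threshold=threshold,
    )


def qc_generated_atac(
    g: GeneratedMatrix,
    min_cells_per_peak: int = 10,
    min_peaks_per_cell: int = 200,
) -> tuple[GeneratedMatrix, QCReport]:
    """Quality control on generated binary peaks.

    Peaks present in fewer than ``min_cells_per_peak`` cells are removed
    first; cells with fewer than ``min_peaks_per_cell`` accessible peaks
    among the survivors are removed second.  Equality is kept at both
    bounds.
    """
    if g.kind != "binary":
        raise ValueError("qc_generated_atac expects binarized peaks")
    values = np.asarray(g.values)
    peak_prev = values.sum(axis=0)
    keep_peaks = peak_prev >= min_cells_per_peak
    trimmed = values[:, keep_peaks]
    cell_counts = trimmed.sum(axis=1)
    keep_cells = cell_counts >= min_peaks_per_cell
    if not keep_peaks.any() or not keep_cells.any():
        raise EmptyAfterQCError("nothing survives the generated-ATAC QC filter")
    out = GeneratedMatrix(
        values=trimmed[keep_cells],
        cell_ids=[c for c, k in zip(g.cell_ids, keep_cells) if k],
        feature_ids=[f for f, k in zip(g.feature_ids, keep_peaks) if k],
        modality="atac",
        kind="binary",
        source_model=g.source_model,
        threshold=g.threshold,
    )
    report = QCReport(
        n_cells_in=values.shape[0],
        n_cells_out=out.values.shape[0],
        n_features_in=values.shape[1],
        n_features_out=out.values.shape[1],
        removed={
            "peaks_below_min_cells": int((~keep_peaks).sum()),
            "cells_below_min_peaks": int((~keep_cells).sum()),
        },
        thresholds={
            "min_cells_per_peak": min_cells_per_peak,
            "min_peaks_per_cell": min_peaks_per_cell,
        },
    )
    return out, report
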