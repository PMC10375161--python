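"""Modality-specific QC, normalisation and the cluster-based data split.

RNA pipeline (in order): cell filter by detected genes, sex-chromosome gene
removal, size normalisation to the median per-cell total, log1p, per-gene
z-scoring.  ATAC: prevalence filter then binarisation.  ADT: centered
log-ratio per cell.  Filter boundaries follow strict inequalities ("fewer
than", "more than"): equality is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from scmog.io import CountMatrix, SplitAssignment

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


@dataclass
class ProcessedMatrix:
    """A CountMatrix after modality-specific transformation.

    ``transform_log`` is the ordered provenance of applied steps; for RNA it
    also carries the per-gene mean/std used for standardisation (``gene_mean``,
    ``gene_std``) so the identical transform can be replayed on new data at
    inference time.
    """

    values: np.ndarray | sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str
    transform_log: list[dict] = field(default_factory=list)
    gene_mean: np.ndarray | None = None
    gene_std: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


@dataclass
class QCReport:
    """Bookkeeping for a filtering step; counts always reconcile with shapes."""

    n_cells_in: int
    n_cells_out: int
    n_features_in: int
    n_features_out: int
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cells_removed = sum(v for k, v in self.removed.items() if k.startswith("cells"))
        feats_removed = sum(v for k, v in self.removed.items() if k.startswith("features") or k.startswith("peaks"))
        if self.n_cells_in - cells_removed != self.n_cells_out:
            raise ValueError("QCReport cell counts do not reconcile")
        if self.n_features_in - feats_removed != self.n_features_out:
            raise ValueError("QCReport feature counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_features_in": self.n_features_in,
            "n_features_out": self.n_features_out,
            "removed": dict(self.removed),
            "thresholds": dict(self.thresholds),
        }


class EmptyAfterQCError(ValueError):
    """All cells or all features were removed by a filter."""


def _detected_per_cell(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values > 0).sum(axis=1)).ravel()
    return (np.asarray(values) > 0).sum(axis=1)


def _prevalence_per_feature(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values > 0).sum(axis=0)).ravel()
    return (np.asarray(values) > 0).sum(axis=0)


def filter_rna_cells(
    m: CountMatrix, min_genes: int = 200, max_genes: int = 7000
) -> tuple[CountMatrix, QCReport]:
    """Remove cells with fewer than ``min_genes`` or more than ``max_genes``
    detected (strictly positive) genes.  Cells exactly at either bound are
    kept.  The mouse convention uses ``max_genes=2500``."""
    if m.modality != "rna":
        raise ValueError("filter_rna_cells expects an RNA matrix")
    detected = _detected_per_cell(m.values)
    too_few = detected < min_genes
    too_many = detected > max_genes
    keep = ~(too_few | too_many)
    if not keep.any():
        raise EmptyAfterQCError("no cells remain after the detected-gene filter")
    out = m.subset_cells(np.flatnonzero(keep))
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_out=out.n_cells,
        n_features_in=m.n_features,
        n_features_out=out.n_features,
        removed={
            "cells_below_min_genes": int(too_few.sum()),
            "cells_above_max_genes": int(too_many.sum()),
        },
        thresholds={"min_genes": min_genes, "max_genes": max_genes},
    )
    return out, report


def drop_sex_chromosome_genes(
    m: CountMatrix, gene_annotation: Mapping[str, str]
) -> CountMatrix:
    """Drop genes annotated to chrX/chrY; unannotated genes are retained."""
    if not gene_annotation:
        logger.info("empty gene annotation: sex-chromosome filter is a no-op")
        return m
    keep = np.array(
        [gene_annotation.get(g) not in SEX_CHROMOSOMES for g in m.feature_ids]
    )
    if keep.all():
        return m
    return m.subset_features(np.flatnonzero(keep))


def size_normalize(m: CountMatrix) -> ProcessedMatrix:
    """Scale each cell so its total equals the median pre-normalisation
    per-cell total."""
    if m.modality != "rna":
        raise ValueError("size_normalize expects an RNA matrix")
    totals = np.asarray(m.values.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts cannot be size-normalized: "
            f"{[m.cell_ids[i] for i in zero[:5]]}"
        )
    median = float(np.median(totals))
    scale = median / totals
    if sp.issparse(m.values):
        values = sp.diags(scale) @ m.values.tocsr()
    else:
        values = np.asarray(m.values, dtype=float) * scale[:, None]
    return ProcessedMatrix(
        values,
        list(m.cell_ids),
        list(m.feature_ids),
        "rna",
        transform_log=[{"step": "size_normalize", "median_total": median}],
    )


def log_and_standardize(
    m: ProcessedMatrix, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> ProcessedMatrix:
    """log1p then per-gene z-score.

    Standardisation uses the population std (ddof=0).  Genes with zero std on
    the fitting data get std replaced by 1, leaving them at 0 after centering
    rather than dropping them, so dimensionality is stable between fit and
    inference.  Pass ``stats=(mean, std)`` recorded from a fitting run to
    replay the transform on new data.
    """
    x = np.log1p(m.dense().astype(float))
    if stats is None:
        mean = x.mean(axis=0)
        std = x.std(axis=0, ddof=0)
        std = np.where(std == 0, 1.0, std)
    else:
        mean, std = (np.asarray(s, dtype=float) for s in stats)
        if mean.shape[0] != x.shape[1] or std.shape[0] != x.shape[1]:
            raise ValueError(
                f"stats cover {mean.shape[0]} genes but matrix has {x.shape[1]}"
            )
    z = (x - mean) / std
    return ProcessedMatrix(
        z,
        list(m.cell_ids),
        list(m.feature_ids),
        "rna",
        transform_log=m.transform_log
        + [{"step": "log1p"}, {"step": "standardize", "ddof": 0, "refit": stats is None}],
        gene_mean=mean,
        gene_std=std,
    )


def filter_atac_peaks(
    m: CountMatrix, min_cells: int = 5, max_frac: float = 0.10
) -> tuple[CountMatrix, QCReport]:
    """Keep peaks present in at least ``min_cells`` cells and in at most
    ``max_frac`` of cells (both bounds inclusive)."""
    if m.modality != "atac":
        raise ValueError("filter_atac_peaks expects an ATAC matrix")
    prev = _prevalence_per_feature(m.values)
    too_rare = prev < min_cells
    too_common = prev > max_frac * m.n_cells
    keep = ~(too_rare | too_common)
    if not keep.any():
        raise EmptyAfterQCError("no peaks remain after the prevalence filter")
    out = m.subset_features(np.flatnonzero(keep))
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_out=out.n_cells,
        n_features_in=m.n_features,
        n_features_out=out.n_features,
        removed={
            "peaks_below_min_cells": int(too_rare.sum()),
            "peaks_above_max_frac": int((too_common & ~too_rare).sum()),
        },
        thresholds={"min_cells": min_cells, "max_frac": max_frac},
    )
    return out, report


def binarize_atac(m: CountMatrix) -> ProcessedMatrix:
    """Accessibility counts to presence/absence: value > 0 becomes 1."""
    if m.modality != "atac":
        raise ValueError("binarize_atac expects an ATAC matrix")
    if sp.issparse(m.values):
        values = (m.values > 0).astype(np.float64).tocsr()
    else:
        values = (np.asarray(m.values) > 0).astype(np.float64)
    return ProcessedMatrix(
        values,
        list(m.cell_ids),
        list(m.feature_ids),
        "atac",
        transform_log=[{"step": "binarize"}],
    )


def clr_transform(adt: CountMatrix, pseudocount: float = 1.0) -> ProcessedMatrix:
    """Centered log-ratio transform of ADT counts, per cell.

    For a cell with tag vector t over d antibodies,
    z_i = ln((t_i + pseudocount) / g(t + pseudocount)) with g the geometric
    mean over the cell's antibodies; each row sums to zero.  The default
    pseudocount of 1 keeps the geometric mean finite when counts contain
    zeros.
    """
    if adt.modality != "adt":
        raise ValueError("clr_transform expects an ADT matrix")
    if adt.n_features < 2:
        raise ValueError("CLR needs at least 2 antibodies")
    t = adt.dense().astype(float) + pseudocount
    if (t <= 0).any():
        raise ValueError("CLR undefined: nonpositive values after pseudocount")
    logt = np.log(t)
    z = logt - logt.mean(axis=1, keepdims=True)
    return ProcessedMatrix(
        z,
        list(adt.cell_ids),
        list(adt.feature_ids),
        "adt",
        transform_log=[{"step": "clr", "pseudocount": pseudocount}],
    )


def random_split(
    n_cells: int,
    seed: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> SplitAssignment:
    """Random train/validation/test split; all three partitions nonempty."""
    if n_cells < 3:
        raise ValueError("need at least 3 cells for a three-way split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    n_val = max(1, int(round(fractions[1] * n_cells)))
    n_test = max(1, int(round(fractions[2] * n_cells)))
    labels = np.array(["train"] * n_cells, dtype=object)
    labels[order[:n_test]] = "test"
    labels[order[n_test : n_test + n_val]] = "validation"
    if (labels == "train").sum() == 0:
        raise ValueError("train partition empty; too few cells")
    return SplitAssignment(labels, method="random")


def cluster_split(
    rna: ProcessedMatrix,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 50,
    fallback_random: bool = True,
) -> SplitAssignment:
    """Leiden-cluster the processed RNA and hold out whole clusters.

    The largest cluster becomes the test set, the second largest the
    validation set, and all remaining cells train the model.  Holding out
    clusters rather than random cells reduces train/test similarity, so the
    test metrics better reflect generalisation.  Falls back to a random
    70/15/15 split (with a warning) when fewer than 3 clusters are found.
    """
    import warnings

    import anndata
    import scanpy as sc

    x = rna.dense().astype(np.float32)
    adata = anndata.AnnData(X=x)
    n_comps = min(n_pcs, min(adata.shape) - 1)
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, random_state=seed)
    with warnings.catch_warnings():
        # scanpy announces a future default-backend change on every call
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata, resolution=resolution, random_state=seed, flavor="leidenalg"
        )
    clusters = adata.obs["leiden"].astype(int).to_numpy()
    uniq, sizes = np.unique(clusters, return_counts=True)
    if len(uniq) < 3:
        if not fallback_random:
            raise ValueError(
                f"only {len(uniq)} Leiden clusters found; need >= 3 for a cluster split"
            )
        logger.warning(
            "only %d Leiden clusters found; falling back to a random split", len(uniq)
        )
        out = random_split(rna.n_cells, seed)
        out.cluster_of_cell = clusters
        return out
    # sort by size descending, ties broken by cluster id for determinism
    order = sorted(range(len(uniq)), key=lambda i: (-sizes[i], uniq[i]))
    test_cluster, val_cluster = uniq[order[0]], uniq[order[1]]
    labels = np.array(["train"] * rna.n_cells, dtype=object)
    labels[clusters == test_cluster] = "test"
    labels[clusters == val_cluster] = "validation"
    return SplitAssignment(labels, method="leiden-two-largest", cluster_of_cell=clusters)


def preprocess_rna(
    m: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 7000,
    gene_annotation: Mapping[str, str] | None = None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ProcessedMatrix, QCReport]:
    """Full RNA pipeline: cell filter -> sex-chromosome drop -> size
    normalise -> log1p -> standardise."""
    filtered, report = filter_rna_cells(m, min_genes=min_genes, max_genes=max_genes)
    filtered = drop_sex_chromosome_genes(filtered, gene_annotation or {})
    normed = size_normalize(filtered)
    return log_and_standardize(normed, stats=stats), report
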