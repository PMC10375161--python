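"""Paired multiomics simulator.

Emulates the statistical regime the translator assumes: a shared per-cell
latent state (cell-type centroid plus noise) drives all modalities, RNA
counts are negative-binomial around a softplus link of the latent with
log-normal library-size heterogeneity, peaks are Bernoulli through a sigmoid
link calibrated to an extreme 0/1 imbalance (3% accessible by default) with
peak dimensionality above gene dimensionality, and ADT counts are an
exponentiated linear readout of the latent with Gaussian noise.  Because one
latent drives everything, a model that recovers it can translate between
modalities — the cross-omics signal the tests look for.

Defaults (2,000 cells x 300 genes x 1,000 peaks x 8 proteins, 4 cell types)
are big enough for the networks to learn from and small enough for
minutes-scale CPU training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.special import expit

from scmog.io import CountMatrix, PairedDataset


@dataclass
class SyntheticSpec:
    """Everything that determines a simulated dataset (given the seed).

    ``linked_fraction`` is the share of genes/peaks whose loadings on the
    latent are nonzero; 0 gives a negative control in which no modality
    carries cell-type signal.  ``library_sd`` is the log-normal sigma of the
    per-cell RNA size factor (0.3 by default so size normalisation has real
    work to do); set 0 for moment-level checks of the NB sampler.
    """

    n_cells: int = 2000
    n_genes: int = 300
    n_peaks: int = 1000
    n_proteins: int = 8
    n_cell_types: int = 4
    latent_dim: int = 16
    rna_dispersion: float = 2.0
    peak_base_rate: float = 0.03
    adt_noise_sd: float = 0.25
    linked_fraction: float = 0.3
    library_sd: float = 0.3
    base_depth: float = 2000.0
    centroid_scale: float = 2.0
    latent_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_peaks", "n_proteins",
                     "n_cell_types", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.peak_base_rate < 1.0:
            raise ValueError("peak_base_rate must be in (0, 1)")
        if self.rna_dispersion <= 0:
            raise ValueError("rna_dispersion must be positive")
        if not 0.0 <= self.linked_fraction <= 1.0:
            raise ValueError("linked_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    cell_types: np.ndarray
    latents: np.ndarray
    rna_loadings: np.ndarray
    atac_loadings: np.ndarray
    adt_loadings: np.ndarray


def _loadings(rng, latent_dim: int, n_features: int, linked_fraction: float,
              scale: float) -> np.ndarray:
    """Loading matrix with only a ``linked_fraction`` of nonzero columns."""
    L = np.zeros((latent_dim, n_features))
    n_linked = int(round(linked_fraction * n_features))
    linked = rng.choice(n_features, size=n_linked, replace=False)
    L[:, linked] = rng.normal(0.0, scale, size=(latent_dim, n_linked))
    return L


def _peak_ids(n_peaks: int) -> list[str]:
    ids = []
    for j in range(n_peaks):
        chrom = f"chr{(j % 22) + 1}"
        start = 1000 * j + 1
        ids.append(f"{chrom}:{start}-{start + 499}")
    return ids


def simulate_paired(
    spec: SyntheticSpec,
) -> tuple[PairedDataset, CountMatrix, SyntheticTruth]:
    """Draw one paired dataset; fully determined by ``spec`` (incl. seed).

    Returns (PairedDataset(rna, atac), adt CountMatrix, SyntheticTruth).
    """
    rng = np.random.default_rng(spec.seed)
    cell_ids = [f"cell_{i:05d}" for i in range(spec.n_cells)]
    gene_ids = [f"gene_{j:04d}" for j in range(spec.n_genes)]
    peak_ids = _peak_ids(spec.n_peaks)
    adt_ids = [f"protein_{j:02d}" for j in range(spec.n_proteins)]

    # shared latent states
    centroids = rng.normal(0.0, spec.centroid_scale,
                           size=(spec.n_cell_types, spec.latent_dim))
    types = rng.integers(0, spec.n_cell_types, size=spec.n_cells)
    latents = centroids[types] + rng.normal(
        0.0, spec.latent_noise_sd, size=(spec.n_cells, spec.latent_dim)
    )

    # RNA: NB counts around a softplus link, log-normal library sizes
    L_rna = _loadings(rng, spec.latent_dim, spec.n_genes, spec.linked_fraction, 0.4)
    baseline_g = rng.normal(0.0, 1.0, size=spec.n_genes)
    rate = np.logaddexp(0.0, latents @ L_rna + baseline_g)  # softplus
    rate /= rate.sum(axis=1, keepdims=True)
    size_factor = (
        np.exp(rng.normal(0.0, spec.library_sd, size=spec.n_cells))
        if spec.library_sd > 0
        else np.ones(spec.n_cells)
    )
    mu = rate * (spec.base_depth * size_factor)[:, None]
    lam = rng.gamma(shape=spec.rna_dispersion, scale=mu / spec.rna_dispersion)
    rna_counts = rng.poisson(lam).astype(np.int64)

    # ATAC: Bernoulli peaks, offset calibrated to the target imbalance
    L_atac = _loadings(rng, spec.latent_dim, spec.n_peaks, spec.linked_fraction, 0.6)
    peak_offset = rng.normal(0.0, 1.5, size=spec.n_peaks)
    logits = latents @ L_atac + peak_offset

    def mean_rate(c: float) -> float:
        return float(expit(logits + c).mean()) - spec.peak_base_rate

    lo, hi = -60.0, 60.0
    if mean_rate(lo) > 0 or mean_rate(hi) < 0:
        raise ValueError(
            f"cannot calibrate peak offset to base rate {spec.peak_base_rate}"
        )
    offset = brentq(mean_rate, lo, hi, xtol=1e-8)
    p = expit(logits + offset)
    atac_counts = sp.csr_matrix(
        (rng.random(size=p.shape) < p).astype(np.int64)
    )

    # ADT: exponentiated linear readout with Gaussian noise
    L_adt = rng.normal(0.0, 0.3, size=(spec.latent_dim, spec.n_proteins))
    baseline_p = rng.normal(3.0, 0.5, size=spec.n_proteins)
    log_abundance = latents @ L_adt + baseline_p
    noisy = log_abundance + rng.normal(0.0, spec.adt_noise_sd, size=log_abundance.shape)
    adt_counts = np.floor(np.exp(noisy)).astype(np.int64)

    rna = CountMatrix(sp.csr_matrix(rna_counts), cell_ids, gene_ids, "rna")
    atac = CountMatrix(atac_counts, cell_ids, peak_ids, "atac")
    adt = CountMatrix(adt_counts, cell_ids, adt_ids, "adt")
    truth = SyntheticTruth(
        cell_types=types,
        latents=latents,
        rna_loadings=L_rna,
        atac_loadings=L_atac,
        adt_loadings=L_adt,
    )
    return PairedDataset(rna, atac), adt, truth


# ---------------------------------------------------------------------------
# micro-fixtures for unit tests


def _counts_with_detected(detected: list[int], n_genes: int) -> CountMatrix:
    """Cells whose i-th row has exactly detected[i] nonzero genes."""
    rows, cols = [], []
    for i, d in enumerate(detected):
        rows.extend([i] * d)
        cols.extend(range(d))
    values = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(detected), n_genes)
    )
    return CountMatrix(
        values,
        [f"cell{i}" for i in range(len(detected))],
        [f"g{j}" for j in range(n_genes)],
        "rna",
    )


def _peaks_with_prevalence(prevalences: list[int], n_cells: int) -> CountMatrix:
    rows, cols = [], []
    for j, prev in enumerate(prevalences):
        rows.extend(range(prev))
        cols.extend([j] * prev)
    values = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_cells, len(prevalences))
    )
    return CountMatrix(
        values,
        [f"cell{i}" for i in range(n_cells)],
        [f"chr1:{j*1000+1}-{j*1000+500}" for j in range(len(prevalences))],
        "atac",
    )


def _generated_qc_toy() -> np.ndarray:
    """20x5 binary matrix: peaks D,E have prevalence < 10; after removing
    them, exactly cells 17-19 fall below a 2-peak cell threshold."""
    m = np.zeros((20, 5))
    m[0:17, 0] = 1          # peak A, prevalence 17
    m[0:17, 1] = 1          # peak B, prevalence 17
    m[0:10, 2] = 1          # peak C...
    m[[17, 19], 2] = 1      # ...prevalence 12
    m[[17, 18], 3] = 1      # peak D, prevalence 2 (< 10)
    m[[17, 19], 4] = 1      # peak E, prevalence 2 (< 10)
    return m


def make_fixture_suite() -> dict:
    """Deterministic micro-fixtures used across the unit tests.

    Each entry documents the property it was built to exercise; the test
    suite re-checks every one.
    """
    rng = np.random.default_rng(12345)
    dense = (rng.random((6, 4)) < 0.4) * rng.integers(1, 9, size=(6, 4))
    roundtrip = CountMatrix(
        sp.csr_matrix(dense),
        [f"bc{i}" for i in range(6)],
        [f"g{j}" for j in range(4)],
        "rna",
    )
    return {
        # 4 cells with detected-gene counts {150, 200, 3000, 7500}:
        # defaults keep exactly the 200 and 3000 cells
        "rna_cell_filter": _counts_with_detected([150, 200, 3000, 7500], 7500),
        # mouse max_genes=2500 keeps only the 2000-gene cell
        "rna_cell_filter_mouse": _counts_with_detected([150, 2000, 2600], 2600),
        # peak prevalences {3,5,8,10,11} over 100 cells: keep {5,8,10}
        "atac_peak_filter": _peaks_with_prevalence([3, 5, 8, 10, 11], 100),
        # per-cell totals {10,20,30} -> all rescaled to the median 20
        "size_normalize": CountMatrix(
            np.array([[4, 6], [12, 8], [10, 20]]),
            ["c0", "c1", "c2"], ["g0", "g1"], "rna",
        ),
        # CLR of (2,8) with pseudocount 0 is (-ln2, +ln2)
        "clr": CountMatrix(
            np.array([[2, 8], [1, 1]]), ["c0", "c1"], ["p0", "p1"], "adt"
        ),
        # brute-force pairwise AUROC = 0.75
        "auroc_toy": {
            "scores": np.array([0.1, 0.4, 0.35, 0.8]),
            "truth": np.array([0, 0, 1, 1]),
        },
        # generated-ATAC QC: 2 peaks then 3 cells removed
        "generated_qc": _generated_qc_toy(),
        # focal-loss spot values at alpha=0.93, gamma=2
        "focal_examples": [
            {"p": 0.5, "y": 1, "expected": 0.93 * 0.25 * np.log(2.0)},
            {"p": 0.5, "y": 0, "expected": 0.07 * 0.25 * np.log(2.0)},
        ],
        # NB(x;1,1) pmf is 2^-(x+1): nll(0)=ln2, nll(1)=ln4
        "nb_examples": [
            {"x": 0, "mu": 1.0, "theta": 1.0, "expected": np.log(2.0)},
            {"x": 1, "mu": 1.0, "theta": 1.0, "expected": np.log(4.0)},
        ],
        # random sparse count matrix for format round-trips
        "mtx_roundtrip": roundtrip,
    }
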