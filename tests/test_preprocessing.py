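"""QC filters, normalisation, CLR, and the cluster-based split."""

import numpy as np
import pytest

from scmog.io import CountMatrix
from scmog.preprocessing import (
    EmptyAfterQCError,
    binarize_atac,
    clr_transform,
    cluster_split,
    drop_sex_chromosome_genes,
    filter_atac_peaks,
    filter_rna_cells,
    log_and_standardize,
    preprocess_rna,
    random_split,
    size_normalize,
)


class TestFilterRnaCells:
    def test_default_thresholds_keep_boundary(self, fixtures):
        # detected genes {150, 200, 3000, 7500}: 200 is kept (only "fewer
        # than 200" is removed), 7500 is dropped
        out, report = filter_rna_cells(fixtures["rna_cell_filter"])
        assert out.n_cells == 2
        assert report.removed == {
            "cells_below_min_genes": 1,
            "cells_above_max_genes": 1,
        }
        assert report.n_cells_in - 2 == report.n_cells_out

    def test_mouse_max_genes(self, fixtures):
        out, report = filter_rna_cells(fixtures["rna_cell_filter_mouse"], max_genes=2500)
        assert out.n_cells == 1
        detected = (out.dense() > 0).sum(axis=1)
        np.testing.assert_array_equal(detected, [2000])

    def test_within_bounds_is_identity(self):
        m = CountMatrix(np.ones((3, 500)), [f"c{i}" for i in range(3)],
                        [f"g{i}" for i in range(500)], "rna")
        out, report = filter_rna_cells(m)
        assert out.n_cells == 3
        assert sum(report.removed.values()) == 0

    def test_all_removed_raises(self):
        m = CountMatrix(np.ones((2, 5)), ["a", "b"], list("vwxyz"), "rna")
        with pytest.raises(EmptyAfterQCError):
            filter_rna_cells(m)  # 5 detected genes < 200


class TestSexChromosomeDrop:
    def test_xy_genes_removed(self):
        m = CountMatrix(np.ones((1, 3)), ["c"], ["g1", "g2", "g3"], "rna")
        out = drop_sex_chromosome_genes(
            m, {"g1": "chr1", "g2": "chrX", "g3": "chrY"}
        )
        assert out.feature_ids == ["g1"]

    def test_empty_annotation_is_noop(self):
        m = CountMatrix(np.ones((1, 2)), ["c"], ["g1", "g2"], "rna")
        assert drop_sex_chromosome_genes(m, {}).feature_ids == ["g1", "g2"]

    def test_autosomal_only_is_identity(self):
        m = CountMatrix(np.ones((1, 2)), ["c"], ["g1", "g2"], "rna")
        out = drop_sex_chromosome_genes(m, {"g1": "chr2", "g2": "7"})
        assert out.feature_ids == ["g1", "g2"]


class TestSizeNormalize:
    def test_totals_scaled_to_median(self, fixtures):
        out = size_normalize(fixtures["size_normalize"])
        np.testing.assert_allclose(np.asarray(out.values).sum(axis=1), [20, 20, 20])
        # scale factors 2, 1, 2/3 applied row-wise
        np.testing.assert_allclose(
            np.asarray(out.values), [[8, 12], [12, 8], [20 / 3, 40 / 3]]
        )

    def test_equal_totals_identity(self):
        m = CountMatrix(np.array([[1, 3], [2, 2]]), ["a", "b"], ["g1", "g2"], "rna")
        np.testing.assert_allclose(np.asarray(size_normalize(m).values), m.dense())

    def test_single_cell_identity(self):
        m = CountMatrix(np.array([[2, 5]]), ["a"], ["g1", "g2"], "rna")
        np.testing.assert_allclose(np.asarray(size_normalize(m).values), [[2, 5]])

    def test_zero_total_cell_named(self):
        m = CountMatrix(np.array([[0, 0], [1, 1]]), ["bad", "ok"], ["g1", "g2"], "rna")
        with pytest.raises(ValueError, match="bad"):
            size_normalize(m)


class TestLogAndStandardize:
    def _proc(self, arr):
        from scmog.preprocessing import ProcessedMatrix

        return ProcessedMatrix(
            np.asarray(arr, dtype=float),
            [f"c{i}" for i in range(len(arr))],
            [f"g{j}" for j in range(len(arr[0]))],
            "rna",
        )

    def test_constant_gene_becomes_zero(self):
        out = log_and_standardize(self._proc([[3, 1], [3, 2]]))
        np.testing.assert_allclose(out.values[:, 0], [0, 0])

    def test_population_std_convention(self):
        # ln1p of {0, e-1} is {0, 1}; population std (ddof=0) is 0.5
        out = log_and_standardize(self._proc([[0, 1], [np.e - 1, 1]]))
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])

    def test_reusing_stats_reproduces_fit(self):
        m = self._proc([[0, 1], [4, 2], [9, 3]])
        fit = log_and_standardize(m)
        replay = log_and_standardize(m, stats=(fit.gene_mean, fit.gene_std))
        np.testing.assert_array_equal(fit.values, replay.values)

    def test_stats_shape_mismatch_raises(self):
        m = self._proc([[0, 1], [4, 2]])
        with pytest.raises(ValueError, match="genes"):
            log_and_standardize(m, stats=(np.zeros(3), np.ones(3)))

    def test_full_pipeline_zero_mean_unit_variance(self, tiny_paired):
        _, paired, _, _ = tiny_paired
        proc, _ = preprocess_rna(paired.primary, min_genes=1, max_genes=10**6)
        np.testing.assert_allclose(proc.values.mean(axis=0), 0, atol=1e-6)
        nonconst = proc.gene_std != 1.0
        np.testing.assert_allclose(
            proc.values.std(axis=0, ddof=0)[nonconst], 1, atol=1e-6
        )


class TestFilterAtacPeaks:
    def test_prevalence_boundaries(self, fixtures):
        # prevalences {3,5,8,10,11} over 100 cells: keep {5,8,10}
        out, report = filter_atac_peaks(fixtures["atac_peak_filter"])
        kept_prev = (out.dense() > 0).sum(axis=0)
        np.testing.assert_array_equal(sorted(kept_prev), [5, 8, 10])
        assert report.removed == {
            "peaks_below_min_cells": 1,
            "peaks_above_max_frac": 1,
        }

    def test_peak_failing_both_rules_counted_once(self):
        m = CountMatrix(
            np.vstack([np.ones((4, 1)), np.zeros((36, 1))]),
            [f"c{i}" for i in range(40)], ["chr1:1-2"], "atac",
        )
        # prevalence 4 over 40 cells: < 5 and > 10%
        with pytest.raises(EmptyAfterQCError):
            filter_atac_peaks(m)

    def test_uniform_prevalence_five_all_kept(self):
        vals = np.zeros((1000, 3))
        vals[:5] = 1
        m = CountMatrix(vals, [f"c{i}" for i in range(1000)],
                        [f"chr1:{j}-{j+1}" for j in range(0, 6, 2)], "atac")
        out, _ = filter_atac_peaks(m)
        assert out.n_features == 3


class TestBinarize:
    def test_values(self):
        m = CountMatrix(np.array([[0, 1, 7]]), ["c"],
                        ["chr1:1-2", "chr1:3-4", "chr1:5-6"], "atac")
        np.testing.assert_array_equal(np.asarray(binarize_atac(m).values), [[0, 1, 1]])

    def test_idempotent(self, tiny_paired):
        _, paired, _, _ = tiny_paired
        once = binarize_atac(paired.secondary)
        again = CountMatrix(once.values, once.cell_ids, once.feature_ids, "atac")
        np.testing.assert_array_equal(
            binarize_atac(again).dense(), once.dense()
        )


class TestClr:
    def test_two_antibody_example(self, fixtures):
        out = clr_transform(fixtures["clr"], pseudocount=0)
        np.testing.assert_allclose(out.values[0], [-np.log(2), np.log(2)], atol=1e-12)
        np.testing.assert_allclose(out.values[1], [0, 0], atol=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 100, size=(50, 17))
        m = CountMatrix(counts, [f"c{i}" for i in range(50)],
                        [f"ab{j}" for j in range(17)], "adt")
        out = clr_transform(m)
        np.testing.assert_allclose(np.asarray(out.values).sum(axis=1), 0, atol=1e-9)

    def test_single_antibody_rejected(self):
        m = CountMatrix(np.array([[3]]), ["c"], ["ab"], "adt")
        with pytest.raises(ValueError, match="2 antibodies"):
            clr_transform(m)


class TestSplits:
    def _blobs(self, sizes, seed=0):
        """Well-separated Gaussian blobs as processed RNA."""
        from scmog.preprocessing import ProcessedMatrix

        rng = np.random.default_rng(seed)
        centers = rng.normal(0, 12, size=(len(sizes), 30))
        rows = np.vstack([
            centers[k] + rng.normal(0, 1, size=(n, 30)) for k, n in enumerate(sizes)
        ])
        return ProcessedMatrix(
            rows, [f"c{i}" for i in range(len(rows))],
            [f"g{j}" for j in range(30)], "rna",
        )

    def test_two_largest_clusters_held_out(self):
        proc = self._blobs([50, 30, 20, 10])
        split = cluster_split(proc, seed=0)
        counts = split.counts()
        assert split.method == "leiden-two-largest"
        assert counts["test"] == 50
        assert counts["validation"] == 30
        assert counts["train"] == 30

    def test_deterministic_under_seed(self):
        proc = self._blobs([40, 25, 15])
        a = cluster_split(proc, seed=3)
        b = cluster_split(proc, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_fallback_to_random_when_few_clusters(self):
        proc = self._blobs([60])
        split = cluster_split(proc, seed=1, resolution=0.01, fallback_random=True)
        assert split.method == "random"
        assert all(v > 0 for v in split.counts().values())

    def test_fallback_disabled_raises(self):
        proc = self._blobs([60])
        with pytest.raises(ValueError, match="clusters"):
            cluster_split(proc, seed=1, resolution=0.01, fallback_random=False)

    def test_random_split_fractions(self):
        split = random_split(200, seed=7)
        counts = split.counts()
        assert counts["train"] == 140 and counts["validation"] == 30 and counts["test"] == 30
        np.testing.assert_array_equal(
            split.labels, random_split(200, seed=7).labels
        )
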