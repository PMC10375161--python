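"""Loss functions against independent closed-form and enumeration oracles,
plus finite-difference checks of the analytic gradients."""

import numpy as np
import pytest
from scipy.special import gammaln

from scmog.losses import (
    FocalParams,
    NBParamsBatch,
    binary_cross_entropy,
    focal_loss,
    focal_loss_grad,
    mse_grad,
    mse_loss,
    nb_nll,
    nb_nll_grad,
    wasserstein_critic_losses,
)


def nb_log_pmf_oracle(x, mu, theta):
    """Independent NB log-pmf: log Gamma-form of the mass function, written
    directly from the distribution's definition."""
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + x * (np.log(mu) - np.log(theta + mu))
    )


class TestBinaryCrossEntropy:
    def test_half_probability(self):
        assert binary_cross_entropy(np.array([0.5]), np.array([1])) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_confident_correct_goes_to_zero(self):
        assert binary_cross_entropy(np.array([1.0 - 1e-9]), np.array([1])) < 1e-6

    def test_class_symmetry(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=50)
        a = binary_cross_entropy(p, np.ones(50))
        b = binary_cross_entropy(1 - p, np.zeros(50))
        assert a == pytest.approx(b, abs=1e-12)

    def test_out_of_range_clamped_not_raised(self):
        assert np.isfinite(binary_cross_entropy(np.array([0.0, 1.0]), np.array([1, 0])))


class TestFocalLoss:
    def test_positive_class_spot_value(self, fixtures):
        ex = fixtures["focal_examples"][0]
        got = focal_loss(np.array([ex["p"]]), np.array([ex["y"]]))
        assert got == pytest.approx(ex["expected"], abs=1e-10)
        assert got == pytest.approx(0.93 * 0.25 * np.log(2), abs=1e-10)

    def test_negative_class_spot_value(self, fixtures):
        ex = fixtures["focal_examples"][1]
        got = focal_loss(np.array([ex["p"]]), np.array([ex["y"]]))
        assert got == pytest.approx(0.07 * 0.25 * np.log(2), abs=1e-10)

    def test_reduces_to_bce_without_focusing_or_weighting(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.99, size=(20, 7))
        y = rng.integers(0, 2, size=(20, 7))
        fl = focal_loss(p, y, FocalParams(alpha=None, gamma=0.0))
        assert fl == pytest.approx(binary_cross_entropy(p, y), abs=1e-14)

    def test_vanishes_as_pt_approaches_one(self):
        assert focal_loss(np.array([1 - 1e-8]), np.array([1])) < 1e-10
        assert focal_loss(np.array([1e-8]), np.array([0])) < 1e-10

    def test_monotone_decreasing_in_pt_for_positives(self):
        p = np.linspace(0.05, 0.95, 40)
        vals = [focal_loss(np.array([pi]), np.array([1])) for pi in p]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FocalParams(alpha=1.5)
        with pytest.raises(ValueError):
            FocalParams(gamma=-1)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, size=(4, 3))
        y = rng.integers(0, 2, size=(4, 3))
        params = FocalParams()
        grad = focal_loss_grad(p, y, params)
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                up, dn = p.copy(), p.copy()
                up[i, j] += eps
                dn[i, j] -= eps
                fd = (focal_loss(up, y, params) - focal_loss(dn, y, params)) / (2 * eps)
                assert grad[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-10)


NB_GRID = [
    (x, mu, theta)
    for x in range(11)
    for mu in (0.5, 1.0, 5.0)
    for theta in (0.5, 1.0, 10.0)
]


class TestNbNll:
    def test_known_pmf_values(self, fixtures):
        for ex in fixtures["nb_examples"]:
            got = nb_nll(
                np.array([ex["x"]]),
                NBParamsBatch(np.array([ex["mu"]]), np.array([ex["theta"]]), eps=0.0),
            )
            assert got == pytest.approx(ex["expected"], abs=1e-12)

    def test_matches_log_pmf_oracle_on_grid(self):
        for x, mu, theta in NB_GRID:
            got = nb_nll(
                np.array([float(x)]),
                NBParamsBatch(np.array([mu]), np.array([theta]), eps=0.0),
            )
            assert got == pytest.approx(-nb_log_pmf_oracle(x, mu, theta), abs=1e-8)

    def test_pmf_normalizes(self):
        xs = np.arange(501, dtype=float)
        for mu in (0.5, 1.0, 5.0):
            for theta in (0.5, 1.0, 10.0):
                nlls = np.array([
                    nb_nll(np.array([x]),
                           NBParamsBatch(np.array([mu]), np.array([theta]), eps=0.0))
                    for x in xs
                ])
                assert np.exp(-nlls).sum() >= 0.999

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nb_nll(np.array([-1.0]), NBParamsBatch(np.array([1.0]), np.array([1.0])))

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ValueError):
            NBParamsBatch(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            NBParamsBatch(np.array([1.0]), np.array([-2.0]))

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 20, size=(3, 4)).astype(float)
        mu = rng.uniform(0.5, 8, size=(3, 4))
        theta = rng.uniform(0.5, 5, size=(3, 4))
        params = NBParamsBatch(mu, theta)
        d_mu, d_theta = nb_nll_grad(x, params)
        eps = 1e-6
        for i in range(3):
            for j in range(4):
                for target, grad in ((mu, d_mu), (theta, d_theta)):
                    up, dn = target.copy(), target.copy()
                    up[i, j] += eps
                    dn[i, j] -= eps
                    if target is mu:
                        f_up = nb_nll(x, NBParamsBatch(up, theta))
                        f_dn = nb_nll(x, NBParamsBatch(dn, theta))
                    else:
                        f_up = nb_nll(x, NBParamsBatch(mu, up))
                        f_dn = nb_nll(x, NBParamsBatch(mu, dn))
                    fd = (f_up - f_dn) / (2 * eps)
                    assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestWasserstein:
    def test_separated_scores(self):
        c, g = wasserstein_critic_losses(np.array([1.0, 1.0]), np.array([0.0, 0.0]))
        assert c == pytest.approx(-1.0)
        assert g == pytest.approx(0.0)

    def test_identical_distributions_give_zero(self):
        s = np.array([0.3, -0.2, 1.4])
        c, _ = wasserstein_critic_losses(s, s)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_fake_shift(self):
        rng = np.random.default_rng(4)
        real, fake = rng.normal(size=10), rng.normal(size=10)
        c0, g0 = wasserstein_critic_losses(real, fake)
        c1, g1 = wasserstein_critic_losses(real, fake + 2.5)
        assert c1 - c0 == pytest.approx(2.5, abs=1e-12)
        assert g1 - g0 == pytest.approx(-2.5, abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_critic_losses(np.array([]), np.array([1.0]))


class TestMse:
    def test_zero_when_equal(self):
        x = np.arange(6.0).reshape(2, 3)
        assert mse_loss(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros((3, 3))
        assert mse_loss(x + 2, x) == pytest.approx(4.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=12), rng.normal(size=12)
        perm = rng.permutation(12)
        assert mse_loss(a, b) == pytest.approx(mse_loss(a[perm], b[perm]), abs=1e-12)

    def test_gradient(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        np.testing.assert_allclose(mse_grad(a, b), 2 * (a - b) / 6, atol=1e-14)


def test_reconstruction_losses_nonnegative():
    rng = np.random.default_rng(7)
    p = rng.uniform(0.01, 0.99, size=30)
    y = rng.integers(0, 2, size=30)
    assert binary_cross_entropy(p, y) >= 0
    assert focal_loss(p, y) >= 0
    x = rng.integers(0, 15, size=30).astype(float)
    assert nb_nll(x, NBParamsBatch(rng.uniform(0.5, 5, 30), rng.uniform(0.5, 5, 30))) >= 0
    assert mse_loss(p, y.astype(float)) >= 0
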