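"""EM mixture fitting, BIC selection, intersections and labelling."""

import math

import numpy as np
import pytest

from mixtail.em import (
    MixtureFit,
    NoCrossoverError,
    categorize,
    fit_gaussian_mixture,
    fit_intersection,
    intersection,
    select_components,
)


def test_single_component_recovers_moments(rng):
    x = rng.normal(5, 1, 500)
    fit = fit_gaussian_mixture(x, 1, seed=0)
    assert fit.means[0] == pytest.approx(x.mean(), abs=1e-9)
    assert fit.variances[0] == pytest.approx(x.var(), abs=1e-9)


def test_two_components_recover_well_separated_clusters(rng):
    lo = rng.normal(0, 0.5, 250)
    hi = rng.normal(10, 0.5, 250)
    fit = fit_gaussian_mixture(np.concatenate([lo, hi]), 2, seed=0)
    assert fit.means[0] == pytest.approx(lo.mean(), abs=0.05)
    assert fit.means[1] == pytest.approx(hi.mean(), abs=0.05)
    np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=0.02)


def test_invalid_component_count():
    with pytest.raises(ValueError):
        fit_gaussian_mixture(np.arange(20.0), 3, seed=0)


def test_bic_difference_is_parameter_penalty():
    base = dict(log_likelihood=-100.0, n=200)
    f1 = MixtureFit(weights=np.array([1.0]), means=np.array([0.0]),
                    variances=np.array([1.0]), **base)
    f2 = MixtureFit(weights=np.array([0.5, 0.5]), means=np.array([0.0, 1.0]),
                    variances=np.array([1.0, 1.0]), **base)
    assert f2.bic - f1.bic == pytest.approx(3 * math.log(200))


def test_variance_floor_prevents_degenerate_bic():
    fit = fit_gaussian_mixture(np.zeros(50) + 3.0, 1, seed=0)
    assert np.isfinite(fit.bic)


def test_selection_prefers_truth(rng, bimodal_sample):
    best, f1, f2 = select_components(rng.normal(5, 1, 500), seed=0)
    assert best.n_components == 1

    best, f1, f2 = select_components(bimodal_sample, seed=0)
    assert best.n_components == 2
    assert f2.bic < f1.bic


def test_selection_at_minimum_sample_size(rng):
    best, _, _ = select_components(rng.normal(0, 1, 10), seed=0)
    assert best.n_components in (1, 2)


def test_intersection_symmetric_midpoint():
    assert intersection(0.5, 3, 1, 0.5, 7, 1) == pytest.approx(5.0)


def test_intersection_matches_grid_scan_oracle():
    w1, m1, v1 = 0.5, 0.0, 1.0
    w2, m2, v2 = 0.5, 6.0, 4.0
    grid = np.linspace(m1, m2, 200001)

    def wpdf(x, w, m, v):
        return w * np.exp(-0.5 * (x - m) ** 2 / v) / np.sqrt(2 * np.pi * v)

    oracle = grid[np.argmin(np.abs(wpdf(grid, w1, m1, v1)
                                   - wpdf(grid, w2, m2, v2)))]
    assert intersection(w1, m1, v1, w2, m2, v2) == pytest.approx(
        oracle, abs=1e-3
    )


def test_intersection_identical_components_error():
    with pytest.raises((NoCrossoverError, ValueError)):
        intersection(0.5, 2.0, 1.0, 0.5, 2.0, 1.0)


def test_categorize_tie_breaks_low(rng):
    fit = MixtureFit(
        weights=np.array([0.5, 0.5]),
        means=np.array([3.0, 7.0]),
        variances=np.array([1.0, 1.0]),
        log_likelihood=0.0,
        n=10,
    )
    labels = categorize(np.array([5.0, 2.0, 8.0]), fit)
    np.testing.assert_array_equal(labels, [1, 1, 2])  # midpoint -> label 1


def test_categorize_well_separated_matches_origin(rng):
    lo = rng.normal(0, 0.5, 100)
    hi = rng.normal(10, 0.5, 100)
    x = np.concatenate([lo, hi])
    fit = fit_gaussian_mixture(x, 2, seed=0)
    labels = categorize(x, fit)
    np.testing.assert_array_equal(labels, [1] * 100 + [2] * 100)


def test_categorize_unimodal_all_ones(rng):
    x = rng.normal(5, 1, 50)
    fit = fit_gaussian_mixture(x, 1, seed=0)
    assert set(categorize(x, fit)) == {1}


def test_posteriors_sum_to_one(bimodal_sample):
    fit = fit_gaussian_mixture(bimodal_sample, 2, seed=0)
    post = fit.posteriors(bimodal_sample)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)


def test_fixed_seed_is_bit_reproducible(bimodal_sample):
    a = fit_gaussian_mixture(bimodal_sample, 2, seed=7)
    b = fit_gaussian_mixture(bimodal_sample, 2, seed=7)
    np.testing.assert_array_equal(a.means, b.means)
    np.testing.assert_array_equal(a.variances, b.variances)
    np.testing.assert_array_equal(a.weights, b.weights)
    assert a.log_likelihood == b.log_likelihood


def test_em_matches_sklearn_reference(bimodal_sample):
    """Independent cross-check: our EM finds a likelihood at least as
    good as sklearn's GaussianMixture, with matching parameters."""
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-6,
                         max_iter=500).fit(bimodal_sample.reshape(-1, 1))
    skl_ll = float(gm.score(bimodal_sample.reshape(-1, 1))) * len(
        bimodal_sample
    )
    ours = fit_gaussian_mixture(bimodal_sample, 2, seed=0)
    assert ours.log_likelihood >= skl_ll - 0.05
    order = np.argsort(gm.means_.ravel())
    np.testing.assert_allclose(ours.means, gm.means_.ravel()[order], atol=0.05)
    np.testing.assert_allclose(
        ours.weights, gm.weights_[order], atol=0.02
    )


def test_parameter_recovery_on_separated_mixtures():
    """Estimated means fall within 3 standard errors of truth >= 95% of
    the time for well-separated mixtures (|mu2 - mu1| >= 4 sd, n=200)."""
    ok = 0
    trials = 200
    for i in range(trials):
        r = np.random.default_rng(10_000 + i)
        sd = r.uniform(0.5, 1.5)
        mu1 = r.uniform(0, 5)
        mu2 = mu1 + 4 * sd + r.uniform(0, 2)
        x = np.concatenate(
            [r.normal(mu1, sd, 100), r.normal(mu2, sd, 100)]
        )
        fit = fit_gaussian_mixture(x, 2, seed=i)
        se = sd / np.sqrt(100)
        if (abs(fit.means[0] - mu1) <= 3 * se
                and abs(fit.means[1] - mu2) <= 3 * se):
            ok += 1
    assert ok / trials >= 0.95


def test_fit_intersection_requires_two_components(rng):
    fit = fit_gaussian_mixture(rng.normal(0, 1, 50), 1, seed=0)
    with pytest.raises(ValueError):
        fit_intersection(fit)
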