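"""Probe filtering, categorical-unimodal calls and probe combining."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixtail.probes import (
    calibrate_r_threshold,
    categorical_unimodal,
    combine_probes,
    dichotomize_at,
    probe_filter,
)

BG = 7.16  # background two-sigma threshold used throughout (log2 units)


def _panel(rng, n_samples=80, n_probes=100, n_background=10):
    """Expression panel with planted all-background probes (below BG)."""
    data = {}
    for i in range(n_probes - n_background):
        data[f"p{i}"] = rng.normal(rng.uniform(8, 12), 1.0, n_samples)
    for i in range(n_background):
        data[f"bg{i}"] = rng.normal(5.0, 0.5, n_samples).clip(max=BG - 0.1)
    return pd.DataFrame(data)


def test_probe_filter_removes_planted_background(rng):
    m = _panel(rng)
    kept, report = probe_filter(m, BG)
    removed = set(report["probe"])
    assert removed == {f"bg{i}" for i in range(10)}
    assert kept.shape[1] == 90


def test_probe_filter_keeps_expressed_probe_regardless_of_variance(rng):
    m = _panel(rng)
    # half the samples above threshold but almost no variance
    m["flat_hi"] = np.where(np.arange(len(m)) % 2 == 0, BG + 0.2, BG - 0.2)
    kept, _ = probe_filter(m, BG)
    assert "flat_hi" in kept.columns


def test_probe_filter_removes_borderline_low_variance_probe(rng):
    m = _panel(rng)
    # 2.5% of samples barely above threshold, negligible variance
    col = np.full(len(m), BG - 0.05)
    col[:2] = BG + 0.01
    m["borderline"] = col
    kept, report = probe_filter(m, BG)
    assert "borderline" not in kept.columns
    row = report.set_index("probe").loc["borderline"]
    assert row["reason"] == "borderline"


@pytest.mark.parametrize(
    "frac,expected",
    [(0.50, True), (1.00, False), (0.00, False), (0.05, False),
     (0.949, True)],
)
def test_categorical_unimodal_criterion(frac, expected):
    n = 1000
    k = int(round(frac * n))
    values = np.concatenate([np.full(n - k, BG - 1.0), np.full(k, BG + 1.0)])
    assert categorical_unimodal(values, "unimodal", BG) is expected


def test_categorical_unimodal_rejects_other_patterns():
    with pytest.raises(ValueError):
        categorical_unimodal(np.ones(10), "bimodal", BG)


def test_dichotomize_at_preserves_missing():
    out = dichotomize_at([1.0, 8.0, np.nan], 5.0)
    assert out[0] == 1 and out[1] == 2 and np.isnan(out[2])


def test_r_threshold_recovery_against_grid_oracle():
    r = np.random.default_rng(8)
    pool = np.concatenate(
        [r.normal(0.2, 0.1, 600), r.normal(0.85, 0.07, 600)]
    )
    thr = calibrate_r_threshold(pool, seed=0)

    grid = np.linspace(0.2, 0.85, 100001)

    def wpdf(x, w, m, s):
        return w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))

    oracle = grid[np.argmin(np.abs(wpdf(grid, 0.5, 0.2, 0.1)
                                   - wpdf(grid, 0.5, 0.85, 0.07)))]
    assert thr == pytest.approx(oracle, abs=0.05)


def test_r_threshold_unimodal_pool_uses_default():
    r = np.random.default_rng(9)
    with pytest.warns(RuntimeWarning):
        thr = calibrate_r_threshold(r.normal(0.5, 0.05, 300), seed=0)
    assert thr == 0.69


def test_r_threshold_empty_errors():
    with pytest.raises(ValueError):
        calibrate_r_threshold([])


def _corr_probes(rng, n=60):
    """Three probes of one gene: two tightly correlated, one discordant."""
    base = np.concatenate([rng.normal(4, 0.5, n // 2),
                           rng.normal(9, 0.5, n - n // 2)])
    m = pd.DataFrame(
        {
            "pA": base + rng.normal(0, 0.3, n),
            "pB": base + rng.normal(0, 0.3, n),
            "pC": rng.normal(7, 1.0, n),  # splice-variant-like
        }
    )
    return m


def test_combine_probes_weighted_mean_hand_example():
    # perfectly correlated probes so they group; the first sample has
    # values 4 and 8 with weights 1/2 and 1/6:
    # (0.5*4 + 8/6) / (0.5 + 1/6) = 5
    m = pd.DataFrame({"p1": [4.0, 5.0, 6.0], "p2": [8.0, 9.0, 10.0]})
    combined, _ = combine_probes(
        m, {"p1": "G", "p2": "G"}, {"p1": 2.0, "p2": 6.0}, r_threshold=0.5
    )
    assert combined["G_weighted"].iloc[0] == pytest.approx(5.0)


def test_combine_probes_equal_weights_is_mean(rng):
    m = _corr_probes(rng)[["pA", "pB"]]
    combined, _ = combine_probes(
        m, {"pA": "G", "pB": "G"}, {"pA": 3.0, "pB": 3.0}, r_threshold=0.69
    )
    np.testing.assert_allclose(
        combined["G_weighted"], m.mean(axis=1), atol=1e-12
    )


def test_combine_probes_groups_and_splice_variant(rng):
    m = _corr_probes(rng)
    p2g = {p: "G" for p in m.columns}
    chi2 = {p: 4.0 for p in m.columns}
    combined, report = combine_probes(m, p2g, chi2, r_threshold=0.69)
    assert set(combined.columns) == {"G_weighted", "G-3"}
    kinds = report.set_index("output")["kind"]
    assert kinds["G_weighted"] == "combined"
    assert kinds["G-3"] == "variant"


def test_combine_probes_single_probe_passthrough(rng):
    m = pd.DataFrame({"p1": rng.normal(5, 1, 30)})
    combined, report = combine_probes(m, {"p1": "G"}, {"p1": 1.0})
    np.testing.assert_array_equal(combined["G"], m["p1"])
    assert report["kind"].tolist() == ["single"]


def test_combine_probes_order_independent(rng):
    m = _corr_probes(rng)
    p2g = {p: "G" for p in m.columns}
    chi2 = {"pA": 2.0, "pB": 5.0, "pC": 3.0}
    c1, _ = combine_probes(m, p2g, chi2, r_threshold=0.69)
    perm = m[["pC", "pB", "pA"]]
    c2, _ = combine_probes(perm, p2g, chi2, r_threshold=0.69)
    np.testing.assert_allclose(
        c1["G_weighted"], c2["G_weighted"], atol=1e-12
    )


def test_combine_probes_missing_chi2_uses_group_mean(rng):
    m = _corr_probes(rng)[["pA", "pB"]]
    with pytest.warns(RuntimeWarning):
        combined, _ = combine_probes(
            m, {"pA": "G", "pB": "G"}, {"pA": 2.0}, r_threshold=0.69
        )
    # pB falls back to pA's weight -> plain mean
    np.testing.assert_allclose(
        combined["G_weighted"], m.mean(axis=1), atol=1e-12
    )


@given(st.integers(min_value=0, max_value=10_000))
@settings(deadline=None, max_examples=60)
def test_combined_value_is_convex_combination(seed):
    r = np.random.default_rng(seed)
    vals = r.uniform(0, 12, size=(8, 3))
    m = pd.DataFrame(vals, columns=["a", "b", "c"])
    chi2 = dict(zip(m.columns, r.uniform(0.5, 10, 3)))
    combined, _ = combine_probes(
        m, {c: "G" for c in m.columns}, chi2, r_threshold=-2
    )
    col = combined["G_weighted"]
    assert (col >= vals.min(axis=1) - 1e-9).all()
    assert (col <= vals.max(axis=1) + 1e-9).all()
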