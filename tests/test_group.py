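"""Group-level inference: smoothing, maps, permutation FWE, conjunction."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from mvpakit.group import (GroupConfig, smooth_map, one_sample_t_map,
                           correlation_map, r_to_t, voxel_fwe, cluster_fwe,
                           conjunction, run_group_analysis, FWHM_TO_SIGMA)


def _ball_mask(shape=(10, 12, 10)):
    ax = [np.arange(n) - (n - 1) / 2 for n in shape]
    i, j, k = np.meshgrid(*ax, indexing="ij")
    semi = [max((n - 2) / 2, 1) for n in shape]
    return (i / semi[0]) ** 2 + (j / semi[1]) ** 2 + (k / semi[2]) ** 2 <= 1


# -------------------------------------------------------------- smoothing ----

def test_smooth_map_fwhm_zero_is_identity():
    v = np.random.default_rng(0).standard_normal((6, 6, 6))
    np.testing.assert_array_equal(smooth_map(v, 0.0), v)


def test_smooth_map_matches_scipy_with_converted_sigma():
    v = np.random.default_rng(1).standard_normal((8, 8, 8))
    got = smooth_map(v, fwhm_mm=6.0, voxel_mm=2.0)
    sigma = 6.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 2.0
    np.testing.assert_allclose(got, ndimage.gaussian_filter(v, sigma),
                               atol=1e-12)
    assert FWHM_TO_SIGMA == pytest.approx(2.3548, abs=1e-4)


def test_smooth_map_handles_nans_and_mask():
    mask = np.zeros((6, 6, 6), bool)
    mask[1:5, 1:5, 1:5] = True
    v = np.where(mask, 1.0, np.nan)
    out = smooth_map(v, 4.0, 2.0, mask=mask)
    assert np.isnan(out[~mask]).all()
    assert np.isfinite(out[mask]).all()


def test_smooth_map_preserves_total_mass():
    v = np.zeros((16, 16, 16))
    v[8, 8, 8] = 5.0
    out = smooth_map(v, 4.0, 2.0)
    assert out.sum() == pytest.approx(5.0, rel=1e-6)


# ------------------------------------------------------------ basic maps ----

def test_one_sample_t_map_matches_scipy():
    mask = _ball_mask()
    rng = np.random.default_rng(2)
    maps = [rng.standard_normal(mask.shape) + 0.25 for _ in range(10)]
    t_map, df = one_sample_t_map(maps, 0.25, mask)
    assert df == 9
    data = np.stack([m[mask] for m in maps])
    t_ref = stats.ttest_1samp(data, popmean=0.25, axis=0).statistic
    np.testing.assert_allclose(t_map[mask], t_ref, atol=1e-10)
    assert np.isnan(t_map[~mask]).all()
    with pytest.raises(ValueError, match="3 subjects"):
        one_sample_t_map(maps[:2], 0.25, mask)


def test_correlation_map_matches_scipy_loop():
    mask = _ball_mask((6, 8, 6))
    rng = np.random.default_rng(3)
    scores = rng.standard_normal(8)
    maps = [rng.standard_normal(mask.shape) + 0.1 * s for s in scores]
    r_map = correlation_map(maps, scores, mask)
    data = np.stack([m[mask] for m in maps])
    r_ref = np.array([stats.pearsonr(scores, data[:, v]).statistic
                      for v in range(data.shape[1])])
    np.testing.assert_allclose(r_map[mask], r_ref, atol=1e-10)
    with pytest.raises(ValueError, match="constant"):
        correlation_map(maps, np.ones(8), mask)
    with pytest.raises(ValueError, match="one score"):
        correlation_map(maps, scores[:5], mask)


def test_r_to_t_reference_values():
    assert r_to_t(0.789, 30) == pytest.approx(6.795, abs=5e-4)
    assert abs(r_to_t(0.789, 30) - 6.81) < 0.02
    assert r_to_t(0.698, 30) == pytest.approx(5.158, abs=5e-4)
    # sqrt(3) for r = sqrt(3)/2, n = 3... use a hand-computable case:
    # r = 0.5, n = 6 -> t = 0.5 * 2 / sqrt(0.75)
    assert r_to_t(0.5, 6) == pytest.approx(1.0 / np.sqrt(0.75))
    with pytest.raises(ValueError):
        r_to_t(0.5, 2)
    with pytest.warns(UserWarning):
        assert r_to_t(1.0, 10) == np.inf


# ---------------------------------------------------------------- FWE ----

def test_voxel_fwe_detects_planted_signal_and_not_noise():
    mask = _ball_mask()
    rng = np.random.default_rng(4)
    signal = np.zeros(mask.shape)
    signal[4:6, 5:7, 4:6] = 1.0
    maps = [0.25 + signal + 0.1 * rng.standard_normal(mask.shape)
            for _ in range(12)]
    thr, sig = voxel_fwe(maps, mask, alpha=0.05, n_perm=300, seed=0,
                         null_value=0.25)
    assert sig[4:6, 5:7, 4:6].all()
    # voxels far from the planted block stay null
    far = mask.copy()
    far[2:8, 3:9, 2:8] = False
    assert not sig[far].any()
    assert thr > 0


def test_voxel_fwe_requires_exactly_one_null_spec():
    mask = _ball_mask((5, 5, 5))
    maps = [np.random.default_rng(i).standard_normal(mask.shape)
            for i in range(6)]
    with pytest.raises(ValueError, match="exactly one"):
        voxel_fwe(maps, mask, n_perm=100)
    with pytest.raises(ValueError, match="exactly one"):
        voxel_fwe(maps, mask, n_perm=100, null_value=0.0,
                  scores=np.arange(6))
    with pytest.raises(ValueError, match="n_perm"):
        voxel_fwe(maps, mask, n_perm=10, null_value=0.0)


def test_voxel_fwe_threshold_is_quantile_of_max_null():
    # the threshold must be reproducible from the same sign-flip stream
    mask = _ball_mask((6, 6, 6))
    rng = np.random.default_rng(5)
    maps = [rng.standard_normal(mask.shape) for _ in range(8)]
    thr1, _ = voxel_fwe(maps, mask, n_perm=200, seed=11, null_value=0.0)
    thr2, _ = voxel_fwe(maps, mask, n_perm=200, seed=11, null_value=0.0)
    assert thr1 == thr2
    # and sit near the analytic Bonferroni-ish range for a t with df = 7
    assert 2.0 < thr1 < 15.0


def test_cluster_fwe_finds_planted_cluster():
    mask = _ball_mask()
    rng = np.random.default_rng(6)
    scores = np.linspace(0, 1, 12)
    block = np.s_[3:7, 4:8, 3:7]
    maps = []
    for s in scores:
        v = 0.1 * rng.standard_normal(mask.shape)
        v[block] += s  # accuracy rises with the score inside the block
        maps.append(v)
    table, sig = cluster_fwe(maps, mask, n_perm=300, seed=1, scores=scores)
    assert len(table) >= 1
    assert table.loc[0, "significant"]
    assert sig[block].mean() > 0.8
    assert table.loc[0, "extent"] == int(sig.sum())
    # peak_t consistent with peak_r
    assert table.loc[0, "peak_t"] == pytest.approx(
        r_to_t(table.loc[0, "peak_r"], 12))


def test_cluster_fwe_empty_table_on_noise():
    mask = _ball_mask((6, 6, 6))
    rng = np.random.default_rng(7)
    maps = [rng.standard_normal(mask.shape) for _ in range(10)]
    table, sig = cluster_fwe(maps, mask, n_perm=200, seed=2, null_value=0.0,
                             forming_p=0.001)
    assert not sig.any()
    assert isinstance(table, pd.DataFrame)
    assert not table["significant"].any() if len(table) else True


def test_cluster_connectivity_18_joins_edges_not_corners():
    # two supra-threshold voxels touching along an edge are one cluster at
    # connectivity 18; touching only at a corner they are one cluster at 26
    # but two clusters at 18
    mask = np.ones((6, 6, 6), bool)
    base = np.zeros(mask.shape)
    edge = base.copy()
    edge[2, 2, 2] = edge[3, 3, 2] = 10.0  # share an edge (two axes differ)
    corner = base.copy()
    corner[2, 2, 2] = corner[3, 3, 3] = 10.0  # all three axes differ
    rng = np.random.default_rng(8)
    for vol, n18, n26 in ((edge, 1, 1), (corner, 2, 1)):
        maps = [vol + 0.01 * rng.standard_normal(mask.shape)
                for _ in range(8)]
        for conn, expected in ((18, n18), (26, n26)):
            table, _ = cluster_fwe(maps, mask, n_perm=100, seed=3,
                                   connectivity=conn, null_value=0.0)
            big = table[table["peak_t"] > 50]
            assert len(big) == expected


def test_conjunction_and_fraction():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    a[0, 0, :2] = True
    b[0, 0, 1:3] = True
    both, frac = conjunction(a, b, total_centers=32)
    assert both.sum() == 1
    assert frac == 1 / 32
    with pytest.raises(ValueError):
        conjunction(a, np.zeros((3, 3, 3), bool), 10)


def test_group_config_validation():
    with pytest.raises(ValueError):
        GroupConfig(connectivity=10)
    with pytest.raises(ValueError):
        GroupConfig(voxel_alpha=0.0)
    with pytest.raises(ValueError):
        GroupConfig(fwhm_mm=-1.0)


def test_run_group_analysis_subject_order_invariance():
    mask = _ball_mask((8, 10, 8))
    rng = np.random.default_rng(9)
    scores = rng.uniform(0.3, 0.9, 8)
    maps = [0.25 + 0.2 * s + 0.05 * rng.standard_normal(mask.shape)
            for s in scores]
    cfg = GroupConfig(n_perm=100, seed=5)
    res = run_group_analysis(maps, scores, 0.25, mask, cfg)
    # permuting subjects (maps and scores together) leaves the observed maps
    # unchanged; only the permutation stream differs, so compare statistics
    order = rng.permutation(len(maps))
    res2 = run_group_analysis([maps[i] for i in order], scores[order],
                              0.25, mask, cfg)
    np.testing.assert_allclose(res.t_map[mask], res2.t_map[mask], atol=1e-10)
    np.testing.assert_allclose(res.r_map[mask], res2.r_map[mask], atol=1e-10)
    assert res.conjunction_fraction <= 1.0
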