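"""Decoding: scaling, cost selection, cross-validation, whole-brain maps."""

import numpy as np
import pytest
import sklearn
from sklearn.svm import SVC

from mvpakit.cohort import BetaSeries
from mvpakit.decoding import (DecodingConfig, chance_level, fit_scaler,
                              apply_scaler, class_cost_weights, select_cost,
                              cv_accuracy, decode_whole_brain)
from mvpakit.searchlight import SphereSpec


# ---------------------------------------------------------------- chance ----

def test_chance_level_balanced_and_imbalanced():
    assert chance_level([18, 18, 18, 18]) == 0.25
    sub = chance_level([6] * 10 + [12])
    assert sub == pytest.approx(504 / 5184)
    assert sub == pytest.approx(0.0972, abs=5e-5)


def test_chance_level_validation():
    with pytest.raises(ValueError):
        chance_level([])
    with pytest.raises(ValueError):
        chance_level([3, 0])


def test_chance_level_matches_monte_carlo():
    # independent oracle: simulate frequency-proportional guessing
    counts = np.array([6] * 10 + [12])
    p = counts / counts.sum()
    rng = np.random.default_rng(12)
    n = 100_000
    truth = rng.choice(len(p), size=n, p=p)
    guess = rng.choice(len(p), size=n, p=p)
    mc = (truth == guess).mean()
    analytic = chance_level(counts)
    se = np.sqrt(analytic * (1 - analytic) / n)
    assert abs(mc - analytic) < 3 * se


# ---------------------------------------------------------------- scaler ----

def test_scaler_matches_manual_zscore():
    rng = np.random.default_rng(1)
    train = rng.standard_normal((20, 5)) * 4 + 2
    test = rng.standard_normal((4, 5))
    sc = fit_scaler(train)
    Z = apply_scaler(sc, test)
    manual = (test - train.mean(0)) / train.std(0)
    np.testing.assert_allclose(Z, np.clip(manual, -3, 3), atol=1e-12)


def test_scaler_clips_outliers_and_zeroes_constant_voxels():
    train = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0]])
    sc = fit_scaler(train)
    Z = apply_scaler(sc, np.array([[100.0, 9.0], [-100.0, 5.0]]))
    assert Z[0, 0] == 3.0 and Z[1, 0] == -3.0
    np.testing.assert_array_equal(Z[:, 1], [0.0, 0.0])  # constant voxel
    with pytest.raises(ValueError):
        fit_scaler(train[:1])


def test_class_cost_weights_inverse_frequency_mean_one():
    w = class_cost_weights(["a"] * 6 + ["b"] * 12)
    assert w["a"] == pytest.approx(4 / 3)
    assert w["b"] == pytest.approx(2 / 3)
    assert np.mean(list(w.values())) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        class_cost_weights(["a", "a"])


# ------------------------------------------------------- naive reference ----

def _naive_fold(train_X, train_y, test_X, cost, clip=3.0, weights=None):
    """Independently coded scale-clip-fit-predict for one fold."""
    mu, sd = train_X.mean(0), train_X.std(0)
    sd_safe = np.where(sd == 0, 1, sd)

    def prep(A):
        Z = np.clip((A - mu) / sd_safe, -clip, clip)
        Z[:, sd == 0] = 0
        return Z

    clf = SVC(C=cost, kernel="linear", class_weight=weights)
    clf.fit(prep(train_X), train_y)
    return clf.predict(prep(test_X))


def _naive_cv(X, y, runs, costs, weighted=False):
    """Independent naive reference: nested leave-one-run-out decoding."""
    correct = 0
    for held in np.unique(runs):
        te, tr = runs == held, runs != held
        if len(costs) == 1:
            best = costs[0]
        else:
            tallies = {}
            for c in costs:
                hits = 0
                for inner in np.unique(runs[tr]):
                    ite = tr & (runs == inner)
                    itr = tr & (runs != inner)
                    w = class_cost_weights(y[itr]) if weighted else None
                    pred = _naive_fold(X[itr], y[itr], X[ite], c, weights=w)
                    hits += (pred == y[ite]).sum()
                tallies[c] = hits
            best = min(c for c in costs if tallies[c] == max(tallies.values()))
        w = class_cost_weights(y[tr]) if weighted else None
        pred = _naive_fold(X[tr], y[tr], X[te], best, weights=w)
        correct += (pred == y[te]).sum()
    return correct / len(y)


def _toy_data(n_runs, trials_per_run, n_vox, signal, seed, n_classes=2):
    rng = np.random.default_rng(seed)
    y = np.tile(np.repeat(np.arange(n_classes),
                          trials_per_run // n_classes), n_runs)
    runs = np.repeat(np.arange(1, n_runs + 1), trials_per_run)
    X = rng.standard_normal((len(y), n_vox))
    X[:, 0] += signal * y
    return X, y.astype(str), runs


def test_cv_accuracy_matches_naive_reference_two_runs():
    # 2 runs x 8 trials: one training run, so a single fixed cost
    X, y, runs = _toy_data(2, 8, 6, signal=1.0, seed=21)
    cfg = DecodingConfig(costs=(1.0,))
    res = cv_accuracy(X, y, runs, cfg)
    assert res.accuracy == pytest.approx(_naive_cv(X, y, runs, (1.0,)))
    assert res.chance == 0.5
    assert len(res.fold_accuracies) == 2
    assert sum(res.confusion.values()) == 16


def test_cv_accuracy_matches_naive_reference_nested():
    for seed in (3, 4, 5):
        X, y, runs = _toy_data(4, 8, 5, signal=0.8, seed=seed)
        cfg = DecodingConfig(costs=(0.1, 1.0, 10.0))
        res = cv_accuracy(X, y, runs, cfg)
        naive = _naive_cv(X, y, runs, (0.1, 1.0, 10.0))
        assert res.accuracy == pytest.approx(naive)


def test_cv_accuracy_matches_naive_reference_weighted():
    rng = np.random.default_rng(9)
    y = np.tile(["a"] * 6 + ["b"] * 2, 3)
    runs = np.repeat([1, 2, 3], 8)
    X = rng.standard_normal((24, 5))
    X[:, 0] += (y == "a") * 0.7
    cfg = DecodingConfig(costs=(0.1, 1.0), class_weighted=True)
    res = cv_accuracy(X, y, runs, cfg)
    naive = _naive_cv(X, y, runs, (0.1, 1.0), weighted=True)
    assert res.accuracy == pytest.approx(naive)


def test_select_cost_matches_naive_tally_and_tie_break():
    X, y, runs = _toy_data(4, 8, 5, signal=0.5, seed=7)
    tr = runs != 4
    cfg = DecodingConfig(costs=(0.1, 1.0, 10.0))
    chosen = select_cost(X[tr], y[tr], runs[tr], cfg)
    tallies = {}
    for c in cfg.costs:
        hits = 0
        for inner in np.unique(runs[tr]):
            ite = tr & (runs == inner)
            itr = tr & (runs != inner)
            pred = _naive_fold(X[itr], y[itr], X[ite], c)
            hits += (pred == y[ite]).sum()
        tallies[c] = hits
    assert chosen == min(c for c in cfg.costs if tallies[c] == max(tallies.values()))


def test_select_cost_single_candidate_and_validation():
    X, y, runs = _toy_data(2, 8, 4, signal=1.0, seed=1)
    assert select_cost(X, y, runs, DecodingConfig(costs=(0.5,))) == 0.5
    one_run = np.ones_like(runs)
    with pytest.raises(ValueError, match="2 training runs"):
        select_cost(X, y, one_run, DecodingConfig(costs=(0.1, 1.0)))


# -------------------------------------------------------- cv properties ----

def test_cv_accuracy_perfect_on_separable_data():
    X, y, runs = _toy_data(3, 8, 4, signal=20.0, seed=2)
    res = cv_accuracy(X, y, runs, DecodingConfig(costs=(1.0,)))
    assert res.accuracy == 1.0


def test_cv_accuracy_missing_class_raises_with_fold_name():
    X, y, runs = _toy_data(3, 8, 4, signal=1.0, seed=2)
    y = y.copy()
    y[runs != 1] = "0"  # class "1" appears only in run 1
    with pytest.raises(ValueError, match="holding out run"):
        cv_accuracy(X, y, runs, DecodingConfig(costs=(1.0,)))


def test_cv_accuracy_at_chance_under_label_permutation(schedule):
    # permute labels within run (preserving per-run class balance) on pure
    # noise: mean accuracy over replicates must sit at the analytic chance
    rng = np.random.default_rng(42)
    cats = schedule.entries["category"].to_numpy()
    runs = schedule.entries["run"].to_numpy()
    cfg = DecodingConfig(costs=(1.0,))
    n_rep = 200
    accs = np.empty(n_rep)
    with sklearn.config_context(assume_finite=True):
        for rep in range(n_rep):
            X = rng.standard_normal((len(cats), 27))
            y = cats.copy()
            for r in np.unique(runs):
                idx = np.flatnonzero(runs == r)
                y[idx] = y[rng.permutation(idx)]
            accs[rep] = cv_accuracy(X, y, runs, cfg).accuracy
    chance = 0.25
    half_width = 2.576 * np.sqrt(chance * (1 - chance) / (n_rep * len(cats)))
    assert abs(accs.mean() - chance) < half_width


def test_train_test_scaling_is_fold_wise():
    # scaling parameters must come from the training runs: a constant offset
    # added to the held-out run pushes every test row past the clip bound, so
    # all test rows become identical and the fold collapses to one predicted
    # class.  If the scaler were (incorrectly) refit on the test rows, the
    # offset would be removed and the fold would stay perfect.
    X, y, runs = _toy_data(3, 8, 4, signal=20.0, seed=6)
    clean = cv_accuracy(X, y, runs, DecodingConfig(costs=(1.0,)))
    assert clean.fold_accuracies[2] == 1.0
    shifted = X.copy()
    shifted[runs == 3] += 1000.0
    res = cv_accuracy(shifted, y, runs, DecodingConfig(costs=(1.0,)))
    assert res.fold_accuracies[2] == 0.5  # one class predicted for all rows


# ------------------------------------------------------------ whole brain ----

def _easy_betas(mask, seed=0):
    rng = np.random.default_rng(seed)
    n_per_run, n_runs = 8, 3
    n = n_per_run * n_runs
    y = np.tile(["a"] * 4 + ["b"] * 4, n_runs)
    runs = np.repeat([1, 2, 3], n_per_run)
    data = rng.standard_normal((n,) + mask.shape)
    data[y == "a"] += 3.0
    data[:, ~mask] = 0.0
    return BetaSeries(data=data, mask=mask, run_labels=runs,
                      categories=np.array(y),
                      subcategories=np.array(y))


def test_decode_whole_brain_map_shape_and_values():
    mask = np.zeros((5, 5, 5), bool)
    mask[1:4, 1:4, 1:4] = True
    betas = _easy_betas(mask)
    amap = decode_whole_brain(betas, SphereSpec(radius=2),
                              DecodingConfig(costs=(1.0,)))
    assert amap.data.shape == mask.shape
    assert np.isnan(amap.data[~mask]).all()
    assert not np.isnan(amap.data[mask]).any()
    assert amap.chance == 0.5
    # the mean shift makes every center decodable
    assert np.nanmean(amap.values) > 0.9


def test_decode_whole_brain_wraps_errors_with_center():
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 1, 1] = True
    betas = _easy_betas(mask)
    betas.categories[betas.run_labels != 1] = "a"  # class b only in run 1
    with pytest.raises(RuntimeError, match=r"center \(1, 1, 1\)"):
        decode_whole_brain(betas, SphereSpec(radius=2),
                           DecodingConfig(costs=(1.0,)))


def test_decoding_config_validation():
    with pytest.raises(ValueError):
        DecodingConfig(costs=(0.0, 1.0))
    with pytest.raises(ValueError):
        DecodingConfig(clip=(1.0, 3.0))
    cfg = DecodingConfig.for_level("subcategory")
    assert cfg.class_weighted
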