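"""Feature reduction/selection and linear naive-Bayes decoding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.naive_bayes import GaussianNB

from erdica.decode import (PooledGaussianNB, aggregate_confusion, build_features,
                           crossvalidate, reduce_resolution, select_features,
                           ConfusionMatrix)


# --- resolution reduction -------------------------------------------------

def test_reduce_constant_and_shapes():
    const = np.full((40, 30), 2.5)
    out = reduce_resolution(const, 10)
    assert out.shape == (4, 3) and np.allclose(out, 2.5)
    assert reduce_resolution(np.zeros((20, 20)), 10).shape == (2, 2)


@given(st.integers(0, 10 ** 6))
def test_reduce_matches_block_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    n_t, n_f = int(rng.integers(5, 35)), int(rng.integers(5, 35))
    x = rng.standard_normal((n_t, n_f))
    out = reduce_resolution(x, 10)
    for bi in range(out.shape[0]):
        for bj in range(out.shape[1]):
            block = x[bi * 10:(bi + 1) * 10, bj * 10:(bj + 1) * 10]
            assert np.isclose(out[bi, bj], block.mean())


def test_reduce_applies_to_stacks():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((7, 25, 13))
    out = reduce_resolution(x, 10)
    assert out.shape == (7, 3, 2)
    assert np.allclose(out[3], reduce_resolution(x[3], 10))


# --- naive Bayes ----------------------------------------------------------

def test_nb_symmetric_boundary():
    X = np.array([[-1.0], [-1.2], [-0.8], [1.0], [1.2], [0.8]])
    y = np.array([0, 0, 0, 1, 1, 1])
    clf = PooledGaussianNB().fit(X, y)
    p = clf.predict_proba([[0.0]])
    assert np.allclose(p, [0.5, 0.5], atol=1e-9)
    assert clf.predict([[0.1]]) == [1] and clf.predict([[-0.1]]) == [0]


def test_nb_posterior_matches_closed_form():
    """Hand-computed Gaussian posteriors on a tiny 2-feature fixture."""
    X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0], [3.0, 3.0]])
    y = np.array(["a", "a", "b", "b"])
    clf = PooledGaussianNB().fit(X, y)
    x = np.array([1.5, 1.5])
    # closed form with the same pooled variances and priors
    means = {"a": X[:2].mean(0), "b": X[2:].mean(0)}
    var = (((X[:2] - means["a"]) ** 2).sum(0) + ((X[2:] - means["b"]) ** 2).sum(0)) / 4
    var = np.maximum(var, 1e-6 * X.var(0) + 1e-12)
    logp = {}
    for c in ("a", "b"):
        logp[c] = np.log(0.5) + np.sum(
            -0.5 * np.log(2 * np.pi * var) - (x - means[c]) ** 2 / (2 * var))
    z = np.logaddexp(logp["a"], logp["b"])
    expect = np.exp(np.array([logp["a"], logp["b"]]) - z)
    got = clf.predict_proba([x])[0]
    assert np.allclose(got, expect, atol=1e-12)


def test_nb_deterministic_and_pooled_linearity():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((60, 4))
    y = rng.integers(0, 3, 60)
    a = PooledGaussianNB().fit(X, y)
    b = PooledGaussianNB().fit(X, y)
    assert np.allclose(a.theta_, b.theta_) and np.allclose(a.var_, b.var_)
    # pooled variances make the class log-odds linear in x
    grid = rng.standard_normal((10, 4))
    lp = a.predict_log_proba(grid)
    odds = lp[:, 1] - lp[:, 0]
    # affine check: odds(x) - odds(0) is linear => second differences vanish
    e = np.zeros(4)
    f0 = a.predict_log_proba([e])[0]
    w = np.array([(a.predict_log_proba([np.eye(4)[j]])[0][1]
                   - a.predict_log_proba([np.eye(4)[j]])[0][0])
                  - (f0[1] - f0[0]) for j in range(4)])
    expect = (f0[1] - f0[0]) + grid @ w
    assert np.allclose(odds, expect, atol=1e-9)


def test_nb_per_class_variant_matches_sklearn():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((300, 5)) + rng.integers(0, 2, 300)[:, None]
    y = rng.integers(0, 4, 300)
    ours = PooledGaussianNB(pooled=False, var_floor_frac=0.0).fit(X, y)
    ref = GaussianNB(var_smoothing=0.0).fit(X, y)
    Xt = rng.standard_normal((1000, 5))
    agree = np.mean(ours.predict(Xt) == ref.predict(Xt))
    assert agree >= 0.999


def test_nb_validation():
    with pytest.raises(ValueError):
        PooledGaussianNB().fit(np.zeros((3, 2)), np.array([0, 1]))
    with pytest.raises(ValueError):
        PooledGaussianNB(priors=[0.7, 0.7]).fit(np.zeros((4, 2)), np.array([0, 0, 1, 1]))


# --- feature selection ----------------------------------------------------

def _trials_with_effect(rng, n_trials=80, n_t=20, n_f=12, points=((10, 3), (12, 5))):
    arr = rng.standard_normal((n_trials, n_t, n_f))
    labels = np.array(["c%d" % (i % 4) for i in range(n_trials)])
    for (ti, fi) in points:
        arr[:, ti, fi] -= 8.0
    return arr, labels


def test_select_and_build_features():
    rng = np.random.default_rng(4)
    arr, labels = _trials_with_effect(rng)
    base = np.arange(5)
    mask = select_features(arr, labels, base, seed=0)
    assert mask[10, 3] and mask[12, 5]
    X, spec = build_features([arr], labels, base, seed=0)
    assert X.shape[0] == 80 and X.shape[1] == len(spec)
    # values are direct lookups
    ci, ti, fi = spec.points[0]
    assert np.allclose(X[:, 0], arr[:, ti, fi])


def test_build_features_empty_selection_errors():
    # constant maps: the grand average coincides with every surrogate draw,
    # so nothing exceeds the acceptance band and no feature survives
    arr = np.zeros((40, 20, 10))
    labels = np.array(["c%d" % (i % 4) for i in range(40)])
    with pytest.raises(ValueError, match="significant"):
        build_features([arr], labels, np.arange(5), seed=0)


# --- cross-validation -----------------------------------------------------

def _separable_specs(rng, n_per=12):
    arrs, labels = [], []
    for c in range(4):
        a = rng.standard_normal((n_per, 20, 10)) * 0.1
        a[:, 5 + c, 2] -= 10.0
        arrs.append(a)
        labels += [f"c{c}"] * n_per
    return np.concatenate(arrs), np.array(labels)


def test_crossvalidation_separable_and_partition():
    rng = np.random.default_rng(6)
    arr, labels = _separable_specs(rng)
    folds = crossvalidate([arr], labels, np.arange(4), k=4, seed=0)
    total = aggregate_confusion(folds)
    assert total.accuracy == 1.0
    assert np.allclose(np.diag(total.normalized).sum(), 100.0)
    assert total.counts.sum() == len(labels)      # folds partition the trials


def test_crossvalidation_null_near_chance():
    rng = np.random.default_rng(7)
    accs = []
    for seed in range(5):
        arr = rng.standard_normal((96, 20, 10))
        arr[:, 10, :] -= 6.0        # significant points exist, but carry no label info
        labels = np.array(["c%d" % (i % 4) for i in range(96)])
        folds = crossvalidate([arr], labels, np.arange(4), k=4, seed=seed)
        accs.append(aggregate_confusion(folds).accuracy)
    assert abs(np.mean(accs) - 0.25) < 0.12


def test_crossvalidation_class_size_guard():
    labels = np.array(["a"] * 3 + ["b"] * 12)
    with pytest.raises(ValueError, match="trials"):
        crossvalidate([np.zeros((15, 10, 10))], labels, np.arange(3), k=5, seed=0)


# --- aggregation ----------------------------------------------------------

def test_aggregate_confusion_arithmetic():
    classes = np.array(["a", "b"])
    m1 = ConfusionMatrix(classes=classes, counts=np.array([[3, 1], [0, 4]]))
    m2 = ConfusionMatrix(classes=classes, counts=np.array([[2, 0], [2, 4]]))
    g = aggregate_confusion([m1, m2])
    assert np.array_equal(g.counts, [[5, 1], [2, 8]])
    assert np.isclose(g.normalized.sum(), 100.0)
    assert np.allclose(g.normalized, 100 * g.counts / 16)
    diag = ConfusionMatrix(classes=classes, counts=np.diag([5, 5]))
    gd = aggregate_confusion([diag, diag])
    assert np.count_nonzero(gd.normalized - np.diag(np.diag(gd.normalized))) == 0
    with pytest.raises(ValueError):
        aggregate_confusion([])
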