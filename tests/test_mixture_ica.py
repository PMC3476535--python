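"""Mixture ICA: likelihood machinery, recovery, model probabilities, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from erdica.mixture_ica import (ICAModel, MixtureICA, amari_index,
                                anova_model_probabilities,
                                classify_trials_by_model)


# --- Amari index ----------------------------------------------------------

def test_amari_identity_and_permutation_scale():
    assert amari_index(np.eye(4), np.eye(4)) == 0.0
    P = np.zeros((4, 4))
    perm = [2, 0, 3, 1]
    for i, j in enumerate(perm):
        P[i, j] = (-1) ** i * (i + 1.5)
    assert amari_index(P, np.eye(4)) < 1e-12


def test_amari_matches_bruteforce():
    rng = np.random.default_rng(0)
    W = rng.standard_normal((8, 8))
    A = rng.standard_normal((8, 8))
    P = np.abs(W @ A)
    n = 8
    total = 0.0
    for i in range(n):
        total += P[i].sum() / P[i].max() - 1
    for j in range(n):
        total += P[:, j].sum() / P[:, j].max() - 1
    assert np.isclose(amari_index(W, A), total / (2 * n * (n - 1)), atol=1e-12)


@given(st.integers(0, 1000))
def test_amari_invariant_to_permutation_and_global_scale(seed):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((5, 5))
    A = rng.standard_normal((5, 5))
    perm = rng.permutation(5)
    c = float(rng.uniform(0.5, 2.0)) * float(rng.choice([-1, 1]))
    assert np.isclose(amari_index(W, A), amari_index((c * W)[perm], A), atol=1e-12)
    assert amari_index(W, A) > 0


# --- fitting --------------------------------------------------------------

def test_single_model_laplacian_recovery():
    """Two mixed Laplacian sources are unmixed to Amari index <= 0.05."""
    scores = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        S = rng.laplace(size=(50_000, 2))
        A = rng.normal(size=(2, 2))
        m = MixtureICA(n_models=1, random_state=seed + 1, max_iter=300).fit(S @ A.T)
        W = m.models_[0].W @ (m.pca_.components_
                              / np.sqrt(m.pca_.explained_variance_)[:, None])
        scores.append(amari_index(W, A))
    assert max(scores) <= 0.05


def test_two_regime_blocks_recovered():
    """Alternating blocks from two 6x6 mixings: the fitted mixture assigns
    samples to regimes nearly as well as the true-model Bayes rule."""
    n = 6
    rng = np.random.default_rng(3)
    A1 = rng.normal(size=(n, n))
    A2 = rng.normal(size=(n, n))
    X = np.empty((40_000, n))
    labels = np.empty(40_000, dtype=int)
    for b in range(40):
        sl = slice(b * 1000, (b + 1) * 1000)
        S = rng.laplace(size=(1000, n))
        X[sl] = S @ (A1 if b % 2 == 0 else A2).T
        labels[sl] = b % 2

    def bayes_acc():
        out = []
        for A in (A1, A2):
            W = np.linalg.inv(A)
            ll = -np.abs(X @ W.T).sum(1) + np.linalg.slogdet(W)[1]
            out.append(ll)
        pred = (out[1] > out[0]).astype(int)
        return max(np.mean(pred == labels), np.mean(pred == 1 - labels))

    m = MixtureICA(n_models=2, random_state=5, max_iter=400).fit(X)
    pred = m.predict(X)
    acc = max(np.mean(pred == labels), np.mean(pred == 1 - labels))
    oracle = bayes_acc()
    assert acc >= 0.95
    assert acc >= oracle - 0.02
    T = len(labels)
    assert np.all(np.diff(m.loglik_trace_) >= -1e-8 * T)


def test_gaussian_data_drives_shape_to_two():
    rng = np.random.default_rng(2)
    m = MixtureICA(n_models=1, random_state=0, max_iter=200).fit(
        rng.normal(size=(30_000, 2)))
    assert np.all(np.abs(m.models_[0].rho - 2.0) <= 0.3)


def test_equivariance_under_linear_transform():
    """Premultiplying the data by an invertible matrix leaves the recovered
    sources (and the Amari score vs the composite mixing) unchanged."""
    rng = np.random.default_rng(4)
    S = rng.laplace(size=(30_000, 3))
    A = rng.normal(size=(3, 3))
    B = rng.normal(size=(3, 3)) + 3 * np.eye(3)

    def unmix(X, seed):
        m = MixtureICA(n_models=1, random_state=seed, max_iter=300).fit(X)
        return m.models_[0].W @ (m.pca_.components_
                                 / np.sqrt(m.pca_.explained_variance_)[:, None])

    a1 = amari_index(unmix(S @ A.T, 1), A)
    a2 = amari_index(unmix(S @ A.T @ B.T, 1), B @ A)
    assert a1 <= 0.08 and a2 <= 0.08


def test_insufficient_samples_rejected():
    with pytest.raises(ValueError, match="samples"):
        MixtureICA(n_models=1, n_components=8).fit(np.random.default_rng(0)
                                                   .normal(size=(100, 8)))


# --- model probabilities --------------------------------------------------

def _toy_mixture(M=2, n=2, identical=False):
    rng = np.random.default_rng(0)
    mix = MixtureICA(n_models=M, n_components=n)
    mix.pca_ = None
    mix.mean_ = np.zeros(n)
    models = []
    for h in range(M):
        W = np.eye(n) if identical else np.eye(n) * (h + 1)
        models.append(ICAModel(W=W.astype(float), c=np.zeros(n),
                               rho=np.full(n, 2.0), beta=np.ones(n)))
    mix.models_ = models
    mix.priors_ = np.full(M, 1.0 / M)
    return mix


def test_model_probability_symmetry_and_normalisation():
    X = np.random.default_rng(1).normal(size=(50, 2))
    mix = _toy_mixture(identical=True)
    p = mix.model_probability(X)
    assert np.allclose(p, [0.5, 0.5])
    single = _toy_mixture(M=1)
    assert np.allclose(single.model_probability(X), [1.0])
    mix2 = _toy_mixture(identical=False)
    p2 = mix2.model_probability(X)
    assert np.isclose(p2.sum(), 1.0)
    resp = mix2.responsibilities(X)
    assert np.allclose(resp.sum(axis=0), 1.0)


def test_segment_probability_concentrates_on_true_regime(fitted_mixica):
    """A segment of knee-regime EEG is assigned to one model with near
    certainty once the mixture has specialised."""
    rec, ev = fitted_mixica["recording"], fitted_mixica["events"]
    mix = fitted_mixica["mixica"]
    knee = ev[ev.joint == "knee"].iloc[0]
    p = mix.model_probability(rec.eeg[:, knee.onset_sample:knee.offset_sample].T)
    assert p.max() > 0.99


def test_classification_mapping_invariance(fitted_mixica):
    rec, ev = fitted_mixica["recording"], fitted_mixica["events"]
    mix = fitted_mixica["mixica"]
    res = classify_trials_by_model(mix, rec.eeg, rec.fs_eeg, ev)
    # swap the models: accuracy must be unchanged, mapping swapped
    swapped = MixtureICA(n_models=2, n_components=mix.n_components)
    swapped.models_ = mix.models_[::-1]
    swapped.priors_ = mix.priors_[::-1]
    swapped.pca_ = mix.pca_
    res2 = classify_trials_by_model(swapped, rec.eeg, rec.fs_eeg, ev)
    assert res2["accuracy"] == res["accuracy"]
    assert res2["mapping"][0] == res["mapping"][1]


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    X = rng.laplace(size=(4000, 3))
    from erdica.mixture_ica import load_mixture, save_mixture

    m = MixtureICA(n_models=1, max_iter=40, random_state=0).fit(X)
    save_mixture(m, tmp_path / "mix")
    back = load_mixture(tmp_path / "mix")
    assert np.allclose(back.models_[0].W, m.models_[0].W)
    assert np.allclose(back.priors_, m.priors_)
    Xq = rng.normal(size=(50, 3))
    assert np.allclose(back.score_models(Xq), m.score_models(Xq))
    assert np.allclose(back.transform(Xq), m.transform(Xq))


# --- ANOVA ----------------------------------------------------------------

def test_anova_identical_groups():
    F, p = anova_model_probabilities([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
    assert F == 0.0 and p == 1.0


def test_anova_complete_separation():
    F, p = anova_model_probabilities([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
    assert p < 0.01


def test_anova_matches_sum_of_squares_oracle():
    rng = np.random.default_rng(6)
    groups = [rng.uniform(size=7), rng.uniform(size=9), rng.uniform(size=5)]
    F, p = anova_model_probabilities(groups)
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(all_x) - len(groups)
    F_oracle = (ss_between / df_b) / (ss_within / df_w)
    assert abs(F - F_oracle) < 1e-10
    assert abs(p - (1 - stats.f.cdf(F_oracle, df_b, df_w))) < 1e-12
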