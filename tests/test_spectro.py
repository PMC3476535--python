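"""Morlet spectrograms, warping, bootstrap masks, ERD statistics."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st
from scipy import stats

from erdica.spectro import (Spectrogram, baseline_normalize, bootstrap_mask,
                            compare_conditions_permutation, compare_effort_ttest,
                            erd_statistic, log_freq_grid, morlet_spectrogram,
                            timewarp, trial_spectrogram)

FS = 512.0


def test_freq_grid_log_uniform():
    f = log_freq_grid()
    assert f.size == 220 and np.isclose(f[0], 3.0) and np.isclose(f[-1], 150.0)
    ratios = f[1:] / f[:-1]
    assert np.ptp(ratios) < 1e-9


def test_sinusoid_peaks_at_nearest_bin():
    t = np.arange(int(6 * FS)) / FS
    x = np.sin(2 * np.pi * 10 * t)
    spec = morlet_spectrogram(x, FS)
    nearest = np.argmin(np.abs(spec.freqs - 10.0))
    assert np.all(np.argmax(spec.values, axis=1) == nearest)


def test_amplitude_doubling_shifts_by_6dB():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(int(4 * FS))
    a = morlet_spectrogram(x, FS).values
    b = morlet_spectrogram(2 * x, FS).values
    assert np.allclose(b - a, 10 * np.log10(4.0), atol=1e-9)


def test_white_noise_power_flat_across_bins():
    """L2-normalized wavelets: white noise has equal expected power at f and 2f."""
    rng = np.random.default_rng(1)
    freqs = np.array([10.0, 20.0])
    p = np.zeros(2)
    for _ in range(200):
        x = rng.standard_normal(int(2 * FS))
        s = morlet_spectrogram(x, FS, freqs=freqs)
        p += 10 ** (s.values / 10).mean(axis=0)
    ratio = p[0] / p[1]
    assert 0.93 < ratio < 1.07


def test_signal_shorter_than_window_rejected():
    with pytest.raises(ValueError, match="window"):
        morlet_spectrogram(np.zeros(100), FS)


def _spec_with_baseline(seed=0, n_t=120, n_f=20, t0=-1.5):
    rng = np.random.default_rng(seed)
    times = t0 + np.arange(n_t) * 0.025
    freqs = log_freq_grid(n_f, 4, 40)
    return Spectrogram(values=rng.standard_normal((n_t, n_f)), times=times, freqs=freqs)


def test_baseline_normalization_properties():
    spec = _spec_with_baseline()
    norm = baseline_normalize(spec)
    sel = (norm.times >= -1.0) & (norm.times < -0.5)
    assert np.abs(norm.values[sel].mean(axis=0)).max() < 1e-9
    shifted = replace(spec, values=spec.values + 7.5)
    norm2 = baseline_normalize(shifted)
    assert np.allclose(norm2.values, norm.values, atol=1e-12)


def test_stationary_signal_normalizes_to_zero():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(int(80 * FS))
    spec = morlet_spectrogram(x, FS, freqs=log_freq_grid(10, 8, 30), t0=-40.0)
    norm = baseline_normalize(spec, baseline=(-39.0, -1.0))
    assert np.abs(norm.values.mean(axis=0)).max() < 1.0      # dB, long average


def test_timewarp_identity_and_affinity():
    spec = _spec_with_baseline(n_t=160)
    dur = 1.5
    warped = timewarp(spec, onset=0.0, offset=dur, target_duration=dur)
    sel = np.isin(np.round(warped.times, 6), np.round(spec.times, 6))
    assert np.allclose(warped.values[: sel.sum()],
                       spec.values[np.isin(np.round(spec.times, 6),
                                           np.round(warped.times, 6))][: sel.sum()],
                       atol=1e-9)
    # values linear in time stay linear with matching endpoints after warping
    lin = replace(spec, values=np.tile(spec.times[:, None], (1, spec.freqs.size)))
    w = timewarp(lin, onset=0.0, offset=1.0, target_duration=2.0)
    inside = (w.times >= 0) & (w.times <= 2.0)
    expect = w.times[inside] * 0.5        # latency maps back linearly
    assert np.allclose(w.values[inside, 0], expect, atol=1e-9)


def test_timewarp_roundtrip():
    # smooth band-limited map: interpolation error bounded by dt^2 |f''| / 8
    spec = _spec_with_baseline(n_t=200)
    smooth = np.sin(2 * np.pi * spec.times / 2.0)[:, None] * (1 + np.arange(spec.freqs.size) / 10)
    spec = replace(spec, values=smooth)
    w = timewarp(spec, onset=0.0, offset=1.0, target_duration=2.0)
    back = timewarp(w, onset=0.0, offset=2.0, target_duration=1.0)
    # compare at exactly matching latencies inside the trial
    bt = np.round(back.times, 6)
    st = np.round(spec.times, 6)
    shared = np.intersect1d(bt[(bt >= 0.1) & (bt <= 0.9)], st)
    bi = np.searchsorted(bt, shared)
    si = np.searchsorted(st, shared)
    assert shared.size > 10
    assert np.abs(back.values[bi] - spec.values[si]).max() < 5e-3


def test_timewarp_rejects_bad_interval():
    with pytest.raises(ValueError):
        timewarp(_spec_with_baseline(), onset=1.0, offset=0.5, target_duration=1.0)


# --- bootstrap ------------------------------------------------------------

def _null_trials(rng, n_trials=60, n_t=120, n_f=15):
    return rng.standard_normal((n_trials, n_t, n_f))


def test_bootstrap_null_calibration_small():
    rng = np.random.default_rng(5)
    fracs = []
    for seed in range(5):
        arr = _null_trials(rng, 100)
        res = bootstrap_mask(arr, baseline_cols=np.arange(20), seed=seed)
        fracs.append(res.mask.mean())
    assert 0.02 <= np.mean(fracs) <= 0.09


def test_bootstrap_detects_planted_erd():
    rng = np.random.default_rng(6)
    arr = _null_trials(rng, 40)
    arr[:, 40:100, :] -= 6.0                     # sustained -6 dB
    res = bootstrap_mask(arr, baseline_cols=np.arange(20), seed=0)
    assert res.mask[40:100].mean() >= 0.8
    assert np.all(res.thresholded[~res.mask] == 0.0)


def test_bootstrap_alpha_one_flags_everything():
    rng = np.random.default_rng(7)
    arr = _null_trials(rng, 30)
    # the degenerate band collapses to the two middle order statistics, so a
    # handful of cells can land exactly inside it
    res = bootstrap_mask(arr, baseline_cols=np.arange(20), alpha=1.0, seed=0)
    assert res.mask.mean() > 0.99


def test_bootstrap_warns_on_few_resamples():
    rng = np.random.default_rng(8)
    with pytest.warns(UserWarning, match="unstable"):
        bootstrap_mask(_null_trials(rng, 10), baseline_cols=np.arange(10),
                       n_boot=20, seed=0)


# --- ERD statistics -------------------------------------------------------

def test_erd_statistic_matches_masked_mean_oracle():
    rng = np.random.default_rng(9)
    n_t, n_f = 50, 30
    grand = rng.standard_normal((n_t, n_f))
    mask = rng.random((n_t, n_f)) < 0.3
    times = np.linspace(-1, 3, n_t)
    freqs = log_freq_grid(n_f, 4, 40)
    stat = erd_statistic(grand, mask, times, freqs, "alpha", (0.0, 2.0))
    sel = mask & ((freqs >= 8) & (freqs <= 12))[None, :] \
        & ((times >= 0) & (times <= 2))[:, None]
    assert np.isclose(stat.mean_db, grand[sel].mean())
    assert stat.n_points == sel.sum()
    empty = erd_statistic(grand, np.zeros_like(mask), times, freqs, "alpha", (0, 2))
    assert np.isnan(empty.mean_db) and empty.n_points == 0


def test_effort_ttest_limits_and_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert compare_effort_ttest(x, x) == (0.0, 1.0)
    t, p = compare_effort_ttest(x + 0.5, x)
    assert np.isinf(t) and p == 0.0
    rng = np.random.default_rng(10)
    a, b = rng.normal(size=8), rng.normal(size=8)
    t, p = compare_effort_ttest(a, b)
    d = a - b
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert np.isclose(t, t_oracle, atol=1e-12)
    assert np.isclose(p, 2 * stats.t.sf(abs(t_oracle), len(d) - 1), atol=1e-12)


def test_condition_permutation_null_and_separated():
    rng = np.random.default_rng(11)
    A = rng.standard_normal((25, 40, 10))
    B = rng.standard_normal((25, 40, 10))
    diff, mask = compare_conditions_permutation(A, B, n_perm=300, seed=0)
    assert 0.01 <= mask.mean() <= 0.12
    diff2, mask2 = compare_conditions_permutation(A + 5.0, B, n_perm=300, seed=0)
    assert mask2.all()
    assert np.allclose(diff2, A.mean(axis=0) + 5.0 - B.mean(axis=0))


def test_condition_permutation_exhaustive_matches_enumeration():
    rng = np.random.default_rng(12)
    A = rng.standard_normal((4, 6, 3))
    B = rng.standard_normal((4, 6, 3)) + 1.0
    d1, m1 = compare_conditions_permutation(A, B, n_perm=10 ** 6, seed=0)
    d2, m2 = compare_conditions_permutation(A, B, n_perm=10 ** 6, seed=99)
    assert np.array_equal(m1, m2) and np.allclose(d1, d2)   # exact: seed-free


def test_trial_spectrogram_fixed_shape():
    rng = np.random.default_rng(13)
    x = rng.standard_normal(int(30 * FS))
    freqs = log_freq_grid(20, 4, 40)
    a = trial_spectrogram(x, FS, 10.0, 13.1, 3.0, freqs=freqs)
    b = trial_spectrogram(x, FS, 20.0, 22.6, 3.0, freqs=freqs)
    assert a.values.shape == b.values.shape
    assert np.allclose(a.times, b.times)
    with pytest.raises(ValueError, match="beyond"):
        trial_spectrogram(x, FS, 0.5, 3.0, 3.0, freqs=freqs)


def test_masked_spectrogram_rendering(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from erdica.viz import plot_masked_spectrogram

    spec = _spec_with_baseline()
    ax = plot_masked_spectrogram(spec.values, spec.times, spec.freqs,
                                 onset=0.0, offset=1.0, title="demo")
    ax.figure.savefig(tmp_path / "spec.png")
    assert (tmp_path / "spec.png").stat().st_size > 0


@given(st.integers(0, 10 ** 6))
def test_db_gain_calibration_property(seed):
    """Scaling the waveform by g shifts every dB value by exactly 20 log10 g."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(600)
    g = float(rng.uniform(0.1, 10.0))
    freqs = np.array([8.0, 15.0])
    a = morlet_spectrogram(x, FS, freqs=freqs)
    b = morlet_spectrogram(g * x, FS, freqs=freqs)
    assert np.allclose(b.values - a.values, 20 * np.log10(g), atol=1e-8)
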