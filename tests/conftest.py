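"""Shared fixtures: montages, simulated subjects, and heavy session products.

Expensive computations (dipole recovery sweeps, the simulated study's
source-level spectrogram products) are session-scoped so the unit tests
and the end-to-end acceptance checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from erdica.headmodel import SphereModel, fibonacci_scalp_montage, fit_dipole, scalp_potential

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sphere():
    return SphereModel()


@pytest.fixture(scope="session")
def montage64(sphere):
    return fibonacci_scalp_montage(64, sphere)


@pytest.fixture(scope="session")
def random_dipoles(sphere):
    """50 random dipoles inside 85% of the brain radius (series-convergent)."""
    rng = np.random.default_rng(7)
    locs, moments = [], []
    for _ in range(50):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        locs.append(u * rng.uniform(0.1, 0.85) * sphere.brain_radius)
        moments.append(rng.standard_normal(3) * 5.0)
    return np.array(locs), np.array(moments)


@pytest.fixture(scope="session")
def dipole_recovery(sphere, montage64, random_dipoles):
    """Forward-then-invert results for the 50 random dipoles, noise-free and
    with 10% RMS topography noise."""
    locs, moments = random_dipoles
    rng = np.random.default_rng(11)
    clean, noisy = [], []
    for r0, q in zip(locs, moments):
        topo = scalp_potential(r0, q, montage64, sphere)
        fit = fit_dipole(topo, montage64, sphere)
        clean.append(fit)
        noise = rng.standard_normal(topo.size)
        noise *= 0.1 * np.sqrt(np.mean(topo ** 2)) / noise.std()
        noisy.append(fit_dipole(topo + noise, montage64, sphere))
    return {"locations": locs, "moments": moments, "clean": clean, "noisy": noisy}


@pytest.fixture(scope="session")
def rejection_fixture():
    """64 correlated channels with one high-variance, one kurtotic and one
    decorrelated channel injected (indices 5, 20, 40)."""
    from scipy import signal as sps
    from erdica.io import Recording

    rng = np.random.default_rng(99)
    n, T = 64, 60 * 512
    pos = fibonacci_scalp_montage(n)
    # spatially smooth base: random smooth maps times band-limited noise
    k = 12
    maps = np.column_stack([np.exp(-np.linalg.norm(pos - pos[rng.integers(n)], axis=1) ** 2
                                   / (2 * 40.0 ** 2)) for _ in range(k)])
    sos = sps.butter(4, [2, 30], btype="bandpass", fs=512, output="sos")
    src = sps.sosfilt(sos, rng.standard_normal((k, T)), axis=1)
    eeg = 10 * maps @ src + 0.5 * rng.standard_normal((n, T))
    eeg[5] = 1200.0 * rng.standard_normal(T)                       # rule 1
    kurt = rng.standard_normal(T)
    spikes = rng.random(T) < 0.001
    kurt[spikes] += 30 * rng.standard_normal(spikes.sum())         # rule 2
    eeg[20] = eeg[20] * 0.2 + 10 * kurt / kurt.std()
    eeg[40] = 10 * rng.standard_normal(T)                          # rule 3
    return Recording(eeg=eeg, fs_eeg=512.0,
                     channel_labels=[f"EEG{i:03d}" for i in range(n)],
                     electrode_positions=pos)


@pytest.fixture(scope="session")
def default_subject():
    """One subject of the default synthetic study (full recording)."""
    from erdica import simulate as sim

    rec, events, sources, gt = sim.simulate_subject(subject_id="S00", seed=11)
    return {"recording": rec, "events": events, "sources": sources, "truth": gt}


@pytest.fixture(scope="session")
def fitted_mixica(default_subject):
    """Preprocessed recording + fitted 2-model mixture ICA for that subject."""
    from erdica.io import trial_sample_mask
    from erdica.mixture_ica import MixtureICA
    from erdica.preprocess import highpass, reject_channels, rereference_average

    rec = rereference_average(reject_channels(highpass(default_subject["recording"]))[0])
    events = default_subject["events"]
    X = rec.eeg[:, trial_sample_mask(events, rec.n_samples)].T
    stride = max(X.shape[0] // 100_000, 1)
    mix = MixtureICA(n_models=2, n_components=16, max_iter=250,
                     random_state=3).fit(X[::stride])
    return {"recording": rec, "mixica": mix, "events": events}


def _subject_products(subj_seed: int):
    """Source-level spectrogram products for one simulated subject.

    Computes, from the ground-truth cortical activations (the signals the
    ICA stage is designed to recover), per-condition bootstrap masks for
    the medial premotor source and reduced-resolution trial spectrograms
    for all non-visual cortical sources.
    """
    from erdica import simulate as sim
    from erdica.decode import reduce_resolution
    from erdica.spectro import (bootstrap_mask, erd_statistic, log_freq_grid,
                                null_pool_columns, trial_spectrogram)

    fs = 512.0
    pre = 3.5          # long pre-trial stretch: the null pool needs pause
    freqs = log_freq_grid()                   # columns clear of the baseline
    ev = sim.make_protocol(seed=subj_seed)
    specs_src = sim.default_sources()
    S, _ = sim.simulate_sources(ev, specs_src, fs, seed=subj_seed + 1)
    target = float(np.median((ev.offset_sample - ev.onset_sample) / fs))

    reduced = []
    out = {"erd": {}, "pattern": {}, "target": target}
    for ci in range(4):                      # sma, premotor L/R, parietal
        arr = np.stack([
            trial_spectrogram(S[ci], fs, e.onset_sample / fs, e.offset_sample / fs,
                              target, freqs=freqs, pre=pre, dtype=np.float32).values
            for e in ev.itertuples(index=False)])
        if ci == 0:
            times = trial_spectrogram(
                S[0], fs, ev.onset_sample[0] / fs, ev.offset_sample[0] / fs,
                target, freqs=freqs, pre=pre, dtype=np.float32).times
            base = null_pool_columns(times)
            inband = (freqs >= 8) & (freqs <= 30)
            intrial = (times >= 0) & (times <= target)
            mid = (times >= 0.85) & (times <= target - 0.85)
            edge = (np.abs(times) <= 0.6) | (np.abs(times - target) <= 0.6)
            for mode in ("isometric", "isotonic"):
                for eff in ("high", "low"):
                    sel = ((ev["mode"] == mode) & (ev["effort"] == eff)).to_numpy()
                    res = bootstrap_mask(arr[sel], base, seed=subj_seed + 17)
                    erd = np.nanmean([
                        erd_statistic(res.grand, res.mask, times, freqs, b,
                                      (0.0, target)).mean_db
                        for b in ("alpha", "beta")])
                    out["erd"][(mode, eff)] = float(erd)
                    sig_neg = res.mask & (res.grand < 0)
                    if mode == "isometric":
                        out["pattern"][("mid", eff)] = float(
                            sig_neg[np.ix_(mid, inband)].mean())
                        out["pattern"][("edge", eff)] = float(
                            sig_neg[np.ix_(edge, inband)].mean())
                    else:
                        cover = (sig_neg[np.ix_(intrial, inband)].mean(axis=1)
                                 > 0.25).mean()
                        out["pattern"][("sustained", eff)] = float(cover)
            out["baseline_cols_reduced"] = np.unique(base // 10)
        reduced.append(reduce_resolution(arr, 10).astype(np.float32))
    out["reduced_specs"] = reduced
    out["labels"] = (ev["mode"] + "_" + ev["effort"]).to_numpy()
    return out


@pytest.fixture(scope="session")
def study_products():
    """Source-level products for the 8 subjects of the default study."""
    return [_subject_products(1000 + 10 * s) for s in range(8)]
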