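"""Synthetic study generator: protocol, ERD calibration, mixing, sensors."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from erdica import simulate as sim
from erdica.headmodel import SphereModel


def test_protocol_counts_and_composition():
    ev = sim.make_protocol(seed=0)
    assert len(ev) == 280                       # 7 exercises x 2 efforts x 20 reps
    iso = (ev["mode"] == "isometric").sum()
    ito = (ev["mode"] == "isotonic").sum()
    assert (iso, ito) == (160, 120)             # 4:3 isometric:isotonic
    assert not len(ev[(ev.joint == "knee") & (ev["mode"] == "isotonic")
                      & (ev.direction == "flexion")])
    durs = (ev.offset_sample - ev.onset_sample) / 512.0
    assert 2.0 < durs.mean() < 4.0
    assert (ev.onset_sample[1:].to_numpy() >= ev.offset_sample[:-1].to_numpy()).all()


def test_protocol_determinism_and_empty():
    a = sim.make_protocol(seed=42)
    b = sim.make_protocol(seed=42)
    pd.testing.assert_frame_equal(a, b)
    c = sim.make_protocol(seed=43)
    assert not a["onset_sample"].equals(c["onset_sample"])
    assert len(sim.make_protocol(reps=0, seed=0)) == 0


def _one_source(depth, profile):
    return [sim.SourceSpec("s", [0.0, -5.0, 60.0],
                           band_amps={"alpha": 5.0},
                           erd_profile=profile,
                           erd_depth={"high": depth, "low": depth})]


def _band_power(x, fs, lo, hi):
    f, p = sps.welch(x, fs=fs, nperseg=512)
    return p[(f >= lo) & (f <= hi)].mean()


def test_zero_depth_no_modulation():
    fs = 512.0
    ev = sim.make_protocol(reps=5, seed=1)[:60].reset_index(drop=True)
    S, _ = sim.simulate_sources(ev, _one_source(0.0, "sustained"), fs,
                                n_samples=int(ev.offset_sample.max() + 5 * fs),
                                seed=3, pink_db=-60)
    trial, inter = [], []
    for e in ev.itertuples(index=False):
        trial.append(_band_power(S[0][e.onset_sample:e.offset_sample], fs, 8, 12))
        inter.append(_band_power(S[0][e.offset_sample + 512:e.offset_sample + 2048],
                                 fs, 8, 12))
    ratio = np.mean(trial) / np.mean(inter)
    assert 0.9 <= ratio <= 1.1


def test_sustained_depth_gives_expected_db():
    """d = 0.5 multiplies amplitude by 0.5 mid-trial: -6.02 dB of power."""
    fs = 512.0
    ev = sim.make_protocol(reps=3, seed=3)[:40].reset_index(drop=True)
    S, _ = sim.simulate_sources(ev, _one_source(0.5, "sustained"), fs,
                                n_samples=int(ev.offset_sample.max() + 5 * fs),
                                seed=4, pink_db=-60, depth_jitter_cv=0.0)
    mid_p, base_p = [], []
    for e in ev.itertuples(index=False):
        c = (e.onset_sample + e.offset_sample) // 2
        mid_p.append(_band_power(S[0][c - 256:c + 256], fs, 8, 12))
        base_p.append(_band_power(S[0][e.onset_sample - 2048:e.onset_sample - 512],
                                  fs, 8, 12))
    db = 10 * np.log10(np.mean(mid_p) / np.mean(base_p))
    assert abs(db - 20 * np.log10(0.5)) <= 1.0


def test_transient_profile_spares_mid_trial():
    fs = 512.0
    ev = sim.make_protocol(reps=3, seed=5)[:40].reset_index(drop=True)
    S, _ = sim.simulate_sources(ev, _one_source(0.6, "transient"), fs,
                                n_samples=int(ev.offset_sample.max() + 5 * fs),
                                seed=6, pink_db=-60, depth_jitter_cv=0.0)
    mid_p, on_p, base_p = [], [], []
    for e in ev.itertuples(index=False):
        c = (e.onset_sample + e.offset_sample) // 2
        mid_p.append(_band_power(S[0][c - 200:c + 200], fs, 8, 12))
        on_p.append(_band_power(S[0][e.onset_sample - 100:e.onset_sample + 200],
                                fs, 8, 12))
        base_p.append(_band_power(S[0][e.onset_sample - 2048:e.onset_sample - 512],
                                  fs, 8, 12))
    mid_db = 10 * np.log10(np.mean(mid_p) / np.mean(base_p))
    on_db = 10 * np.log10(np.mean(on_p) / np.mean(base_p))
    assert abs(mid_db) <= 1.0
    assert on_db < -2.0


def test_depth_ordering_enforced():
    with pytest.raises(ValueError):
        sim.SourceSpec("bad", [0, 0, 50], erd_depth={"high": 0.2, "low": 0.5})


def test_recording_rank_one_without_noise(sphere):
    ev = sim.make_protocol(reps=1, seed=7, exercises=[("knee", "isometric", "flexion")])
    spec = _one_source(0.3, "transient")
    S, info = sim.simulate_sources(ev, spec, 512.0, seed=8)
    rec, gt = sim.simulate_recording(S, ev, spec, sphere=sphere, n_channels=16,
                                     seed=9, sensor_noise_uv=0, line_amp_uv=0,
                                     drift_step_uv=0, n_background=0,
                                     extra_info=info)
    sv = np.linalg.svd(rec.eeg, compute_uv=False)
    assert sv[1] < 1e-8 * sv[0]
    # and the mixing model holds exactly
    assert np.allclose(rec.eeg, gt.mixing["knee"] @ S)


def test_regime_segments_follow_upcoming_trial():
    ev = pd.DataFrame({
        "onset_sample": [100, 300], "offset_sample": [200, 400],
        "joint": ["ankle", "knee"], "mode": ["isometric", "isometric"],
        "direction": ["flexion", "flexion"], "effort": ["high", "low"],
    })
    reg = sim.regime_per_sample(ev, 500)
    assert set(reg[:200]) == {"ankle"}      # pre-trial gap inherits trial 1
    assert set(reg[200:400]) == {"knee"}    # gap before trial 2 inherits it
    assert set(reg[400:]) == {"knee"}


def test_mechanical_channels_follow_mode(default_subject):
    rec, ev = default_subject["recording"], default_subject["events"]
    fs, fa = rec.fs_eeg, rec.fs_aux
    force, angle = rec.aux["force"], rec.aux["angle"]
    for e in ev.sample(30, random_state=0).itertuples(index=False):
        lo = int(e.onset_sample / fs * fa)
        hi = int(e.offset_sample / fs * fa)
        mid = slice((lo + hi) // 2 - 200, (lo + hi) // 2 + 200)
        if e.mode == "isometric":
            assert np.abs(force[mid]).mean() > 50
        else:
            assert np.abs(angle[mid]).mean() > 5
    # outside all trials both stay near their noise floor
    gap = slice(0, int(2 * fa))
    assert np.abs(force[gap]).mean() < 10
    assert np.abs(angle[gap]).mean() < 2


def test_mixing_columns_are_forward_maps(default_subject, sphere):
    gt = default_subject["truth"]
    from erdica.headmodel import scalp_potential

    for reg in ("knee", "ankle"):
        for j, spec in enumerate(gt.source_specs):
            loc = spec.location.copy()
            if reg == "ankle" and spec.regime_shift is not None:
                loc = loc + spec.regime_shift
            direction = (spec.moment_direction if spec.moment_direction is not None
                         else loc / np.linalg.norm(loc))
            topo = scalp_potential(loc, direction, gt.electrode_positions, sphere)
            topo = topo / np.max(np.abs(topo))
            assert np.allclose(gt.mixing[reg][:, j], topo, atol=1e-12)


def test_regime_oracle_likelihood_ratio(default_subject):
    """The regime label is recoverable per trial by a Gaussian likelihood
    ratio built from the true mixing matrices and source variances."""
    from erdica.preprocess import highpass

    rec, ev, gt = (default_subject["recording"], default_subject["events"],
                   default_subject["truth"])
    S = default_subject["sources"]
    eeg = highpass(rec).eeg                     # drift removed, as analysed
    A_bg = gt.background_mixing
    bg_var = 3.0 ** 2
    noise_var = 1.0 ** 2 + 0.5 ** 2 / 2 + 0.25  # sensor + line + margin
    n = eeg.shape[0]
    correct = 0
    for e in ev.itertuples(index=False):
        seg = eeg[:, e.onset_sample:e.offset_sample]
        d_src = S[:, e.onset_sample:e.offset_sample].var(axis=1)
        scatter = seg @ seg.T
        ll = {}
        for reg in ("knee", "ankle"):
            A = gt.mixing[reg]
            cov = (A * d_src) @ A.T + bg_var * (A_bg @ A_bg.T) + noise_var * np.eye(n)
            sign, logdet = np.linalg.slogdet(cov)
            ll[reg] = -0.5 * (seg.shape[1] * logdet
                              + np.trace(np.linalg.solve(cov, scatter)))
        correct += (max(ll, key=ll.get) == e.joint)
    assert correct / len(ev) >= 0.99


def test_study_determinism():
    a = sim.simulate_subject(seed=123, reps=1, n_channels=16)[0]
    b = sim.simulate_subject(seed=123, reps=1, n_channels=16)[0]
    assert np.array_equal(a.eeg, b.eeg)
    assert np.array_equal(a.aux["force"], b.aux["force"])
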