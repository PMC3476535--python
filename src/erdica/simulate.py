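"""Synthetic EEG generator for the isometric/isotonic knee/ankle protocol.

The generator emulates the statistical structure the analysis chain
assumes, not biophysical detail:

* A protocol of 7 exercises (isometric knee flexion/extension, isotonic
  knee extension, isometric and isotonic ankle plantar-/dorsiflexion - no
  isotonic knee flexion) x 2 effort levels x 20 repetitions, ~3 s trials
  with 5 s pauses, presented in shuffled blocks.
* Cortical sources are amplitude-modulated band-limited Gaussian noise in
  the alpha (8-12 Hz) and beta (12-30 Hz) bands over a pink (1/f)
  background.  The ERD envelope multiplies source amplitude by
  ``1 - d * m(t)``: for isometric trials ``m`` is a pair of 600 ms
  raised-cosine bumps at force onset and offset (transient profile), for
  isotonic trials a plateau spanning the trial with 300 ms cosine ramps
  (sustained profile).  The depth ``d`` is larger at high effort, so the
  steady-state power ERD in dB is ``20*log10(1 - d)``.
* Two spatial regimes: knee-trial samples mix through one matrix, ankle
  trials through another that differs only in the limb-specific premotor
  source, displaced 15 mm posteriorly (the somatotopic shift hypothesis).
  Inter-trial samples take the regime of the upcoming trial.
* Artifacts: Poisson blinks (ocular), broadband 20-150 Hz bursts during
  trials (muscular), white sensor noise, 60 Hz line noise and per-channel
  random-walk drift.
* Auxiliary channels at their own rate: a trapezoidal load-cell force per
  isometric trial and a triangular goniometer excursion per isotonic trial.

Mixing columns are forward-model scalp maps from the spherical head model,
normalized to unit peak so band amplitudes are expressed in microvolts at
the strongest electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .headmodel import SphereModel, scalp_potential, fibonacci_scalp_montage
from .io import Recording, validate_events

__all__ = [
    "EXERCISES",
    "SourceSpec",
    "GroundTruth",
    "default_sources",
    "make_protocol",
    "simulate_sources",
    "simulate_recording",
    "simulate_subject",
    "simulate_study",
]

# (joint, mode, direction); ankle dorsiflexion maps to "flexion",
# plantar flexion to "extension".  Isotonic knee flexion is absent.
EXERCISES = [
    ("knee", "isometric", "flexion"),
    ("knee", "isometric", "extension"),
    ("knee", "isotonic", "extension"),
    ("ankle", "isometric", "flexion"),
    ("ankle", "isometric", "extension"),
    ("ankle", "isotonic", "flexion"),
    ("ankle", "isotonic", "extension"),
]

BAND_EDGES = {"alpha": (8.0, 12.0), "beta": (12.0, 30.0)}


@dataclass
class SourceSpec:
    """One simulated source: location, projection, rhythm and task coupling."""

    name: str
    location: np.ndarray                    # (3,) mm, head frame
    moment_direction: np.ndarray | None = None   # None -> radial
    band_amps: dict = field(default_factory=lambda: {"alpha": 5.0, "beta": 4.0})  # uV at peak electrode
    erd_profile: str = "auto"               # auto | transient | sustained | none
    erd_depth: dict = field(default_factory=lambda: {"high": 0.5, "low": 0.35})
    role: str = "cortical"                  # cortical | ocular | muscular
    regime_shift: np.ndarray | None = None  # added to location in the ankle regime

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        if self.moment_direction is not None:
            m = np.asarray(self.moment_direction, dtype=float)
            self.moment_direction = m / np.linalg.norm(m)
        if self.erd_depth["high"] < self.erd_depth["low"]:
            raise ValueError("erd_depth must be at least as deep at high effort")
        if self.erd_profile not in {"auto", "transient", "sustained", "none"}:
            raise ValueError(f"unknown erd_profile {self.erd_profile!r}")


def default_sources(sphere: SphereModel | None = None,
                    regime_shift_mm: float = 15.0) -> list[SourceSpec]:
    """The default source population for one simulated subject.

    One medial premotor source is limb-specific: its location shifts
    posteriorly (-Y) by ``regime_shift_mm`` for ankle trials.  The visual
    source carries essentially no task information and exists so the
    decoder's exclude-visual control has something to exclude.
    """
    sphere = sphere or SphereModel()
    r = sphere.radius / 85.0      # defaults are expressed for an 85 mm head
    return [
        SourceSpec("sma_limb", np.array([-6.0, -4.0, 62.0]) * r,
                   band_amps={"alpha": 5.0, "beta": 6.0},
                   erd_depth={"high": 0.50, "low": 0.35},
                   regime_shift=np.array([0.0, -regime_shift_mm, 0.0])),
        SourceSpec("premotor_left", np.array([-30.0, -12.0, 55.0]) * r,
                   band_amps={"alpha": 5.0, "beta": 4.0},
                   erd_depth={"high": 0.45, "low": 0.30}),
        SourceSpec("premotor_right", np.array([28.0, -14.0, 54.0]) * r,
                   band_amps={"alpha": 5.0, "beta": 4.0},
                   erd_depth={"high": 0.45, "low": 0.30}),
        SourceSpec("post_parietal", np.array([-2.0, -56.0, 46.0]) * r,
                   band_amps={"alpha": 6.0, "beta": 3.0},
                   erd_depth={"high": 0.40, "low": 0.27}),
        SourceSpec("visual", np.array([3.0, -72.0, 24.0]) * r,
                   band_amps={"alpha": 7.0, "beta": 2.5},
                   erd_depth={"high": 0.10, "low": 0.10}),
        SourceSpec("ocular", np.array([0.0, 72.0, -25.0]) * r,
                   band_amps={}, erd_profile="none",
                   erd_depth={"high": 0.0, "low": 0.0}, role="ocular"),
        SourceSpec("muscular",
                   np.array([0.0, -50.0, -52.0]) * (0.97 * sphere.radius / np.linalg.norm([0, -50, -52])),
                   band_amps={}, erd_profile="none",
                   erd_depth={"high": 0.0, "low": 0.0}, role="muscular"),
    ]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    source_specs: list
    source_signals_key: list            # source names, row order of the signal matrix
    mixing: dict                        # regime -> (n_channels, n_sources)
    regime_per_sample: np.ndarray       # "knee"/"ankle" per EEG sample
    trial_depths: np.ndarray            # (n_trials, n_cortical) realised ERD depths
    blink_times: np.ndarray             # seconds
    electrode_positions: np.ndarray
    background_mixing: np.ndarray | None = None   # diffuse-background columns


# --- protocol -------------------------------------------------------------

def make_protocol(reps: int = 20, trial_duration: float = 3.0,
                  duration_cv: float = 0.1, pause: float = 5.0,
                  fs: float = 512.0, seed: int | None = 0,
                  exercises=None) -> pd.DataFrame:
    """Event table for the full protocol (block order shuffled by ``seed``).

    Each exercise x effort combination forms one block of ``reps``
    consecutive repetitions; trial durations are log-normal around
    ``trial_duration`` with coefficient of variation ``duration_cv``.
    """
    exercises = list(exercises) if exercises is not None else list(EXERCISES)
    rng = np.random.default_rng(seed)
    blocks = [(ex, eff) for ex in exercises for eff in ("high", "low")]
    rng.shuffle(blocks)
    sigma = np.sqrt(np.log(1 + duration_cv ** 2))
    mu = np.log(trial_duration) - sigma ** 2 / 2
    rows = []
    t = pause
    for (joint, mode, direction), effort in blocks:
        for _ in range(int(reps)):
            dur = float(rng.lognormal(mu, sigma))
            rows.append({
                "onset_sample": int(round(t * fs)),
                "offset_sample": int(round((t + dur) * fs)),
                "joint": joint, "mode": mode,
                "direction": direction, "effort": effort,
            })
            t += dur + pause
    events = pd.DataFrame(rows, columns=["onset_sample", "offset_sample",
                                         "joint", "mode", "direction", "effort"])
    return validate_events(events) if len(events) else events


def protocol_n_samples(events: pd.DataFrame, fs: float, tail: float = 5.0) -> int:
    if not len(events):
        return int(round(tail * fs))
    return int(events["offset_sample"].max() + round(tail * fs))


# --- source synthesis -----------------------------------------------------

def _bandpass_noise(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / (x.std() + 1e-30)


def _pink_noise(n: int, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    pink = np.fft.irfft(spec / np.sqrt(f), n)
    return pink / (pink.std() + 1e-30)


def _raised_cosine_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    arg = (t - center) / width
    out = np.zeros_like(t)
    sel = np.abs(arg) < 0.5
    out[sel] = 0.5 * (1 + np.cos(2 * np.pi * arg[sel]))
    return out


def _sustained_window(t: np.ndarray, onset: float, offset: float, ramp: float) -> np.ndarray:
    out = np.zeros_like(t)
    rise = (t >= onset) & (t < onset + ramp)
    out[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - onset) / ramp))
    out[(t >= onset + ramp) & (t <= offset - ramp)] = 1.0
    fall = (t > offset - ramp) & (t <= offset)
    out[fall] = 0.5 * (1 - np.cos(np.pi * (offset - t[fall]) / ramp))
    return out


def _erd_envelope(t: np.ndarray, events: pd.DataFrame, fs: float, spec: SourceSpec,
                  depths: np.ndarray) -> np.ndarray:
    """Per-sample amplitude multiplier ``1 - d * m(t)`` for one source."""
    env = np.ones_like(t)
    n = t.size
    for i, ev in enumerate(events.itertuples(index=False)):
        onset, offset = ev.onset_sample / fs, ev.offset_sample / fs
        profile = spec.erd_profile
        if profile == "auto":
            profile = "transient" if ev.mode == "isometric" else "sustained"
        if profile == "none":
            continue
        lo = max(int((onset - 0.6) * fs), 0)
        hi = min(int((offset + 0.6) * fs) + 1, n)
        tl = t[lo:hi]
        if profile == "transient":
            m = np.minimum(_raised_cosine_bump(tl, onset, 0.6)
                           + _raised_cosine_bump(tl, offset, 0.6), 1.0)
        else:
            m = _sustained_window(tl, onset, offset, 0.3)
        env[lo:hi] -= depths[i] * m
    return np.maximum(env, 0.0)


def simulate_sources(events: pd.DataFrame, source_specs, fs: float,
                     n_samples: int | None = None, seed: int | None = 0,
                     pink_db: float = -10.0, depth_jitter_cv: float = 0.15,
                     blink_rate: float = 0.2, blink_amp: float = 80.0,
                     muscle_amp: float = 4.0):
    """Synthesize all source activations; returns ``(S, info)``.

    ``S`` is (n_sources, n_samples) in the row order of ``source_specs``.
    ``info`` carries the realised per-trial ERD depths (trials x cortical
    sources) and blink times, for ground-truth checks.
    """
    if len(events):
        validate_events(events)
    rng = np.random.default_rng(seed)
    if n_samples is None:
        n_samples = protocol_n_samples(events, fs)
    t = np.arange(n_samples) / fs
    n_trials = len(events)
    cortical = [s for s in source_specs if s.role == "cortical"]
    sigma_j = np.sqrt(np.log(1 + depth_jitter_cv ** 2))

    depths = np.zeros((n_trials, len(cortical)))
    for j, spec in enumerate(cortical):
        base = events["effort"].map(spec.erd_depth).to_numpy(dtype=float) if n_trials else np.empty(0)
        jitter = rng.lognormal(-sigma_j ** 2 / 2, sigma_j, size=n_trials)
        depths[:, j] = np.clip(base * jitter, 0.0, 0.95)

    S = np.zeros((len(source_specs), n_samples))
    blink_times = np.empty(0)
    ci = 0
    for row, spec in enumerate(source_specs):
        if spec.role == "cortical":
            env = _erd_envelope(t, events, fs, spec, depths[:, ci])
            x = np.zeros(n_samples)
            for band, amp in spec.band_amps.items():
                lo, hi = BAND_EDGES[band]
                x += amp * env * _bandpass_noise(n_samples, fs, lo, hi, rng)
            alpha_amp = spec.band_amps.get("alpha", max(spec.band_amps.values(), default=1.0))
            x += alpha_amp * 10 ** (pink_db / 20) * _pink_noise(n_samples, rng)
            S[row] = x
            ci += 1
        elif spec.role == "ocular":
            x = np.zeros(n_samples)
            times = []
            tt = rng.exponential(1 / blink_rate)
            pulse_n = int(round(0.3 * fs))
            pulse = (np.sin(2 * np.pi * np.arange(pulse_n) / pulse_n)
                     * np.hanning(pulse_n))
            while tt < t[-1] - 0.4:
                i0 = int(tt * fs)
                x[i0:i0 + pulse_n] += blink_amp * rng.normal(1.0, 0.2) * pulse
                times.append(tt)
                tt += rng.exponential(1 / blink_rate)
            S[row] = x
            blink_times = np.array(times)
        elif spec.role == "muscular":
            gate = np.zeros(n_samples)
            for ev in events.itertuples(index=False):
                lo, hi = int(ev.onset_sample), min(int(ev.offset_sample) + 1, n_samples)
                g = _sustained_window(t[lo:hi], ev.onset_sample / fs,
                                      ev.offset_sample / fs, 0.1)
                gate[lo:hi] = np.maximum(gate[lo:hi],
                                         g * (1.5 if ev.effort == "high" else 1.0))
            S[row] = muscle_amp * gate * _bandpass_noise(n_samples, fs, 20.0,
                                                         min(150.0, fs / 2 - 1), rng)
        else:
            raise ValueError(f"unknown source role {spec.role!r}")
    info = {"trial_depths": depths, "blink_times": blink_times}
    return S, info


# --- mixing and sensors ---------------------------------------------------

def _mixing_matrix(source_specs, electrode_positions: np.ndarray,
                   sphere: SphereModel, regime: str) -> np.ndarray:
    cols = []
    for spec in source_specs:
        loc = spec.location.copy()
        if regime == "ankle" and spec.regime_shift is not None:
            loc = loc + spec.regime_shift
        direction = (spec.moment_direction if spec.moment_direction is not None
                     else loc / (np.linalg.norm(loc) + 1e-12))
        topo = scalp_potential(loc, direction, electrode_positions, sphere)
        cols.append(topo / np.max(np.abs(topo)))
    return np.column_stack(cols)


def regime_per_sample(events: pd.DataFrame, n_samples: int) -> np.ndarray:
    """Per-sample regime label; gaps inherit the upcoming trial's regime."""
    out = np.empty(n_samples, dtype=object)
    if not len(events):
        out[:] = "knee"
        return out
    prev_end = 0
    for ev in events.itertuples(index=False):
        out[prev_end:ev.offset_sample] = ev.joint
        prev_end = ev.offset_sample
    out[prev_end:] = events.iloc[-1]["joint"]
    return out


def simulate_recording(sources: np.ndarray, events: pd.DataFrame,
                       source_specs, sphere: SphereModel | None = None,
                       electrode_positions: np.ndarray | None = None,
                       n_channels: int = 64, fs: float = 512.0,
                       fs_aux: float = 1000.0, seed: int | None = 0,
                       sensor_noise_uv: float = 1.0, line_amp_uv: float = 0.5,
                       line_freq: float = 60.0, drift_step_uv: float = 0.01,
                       n_background: int = 24, background_amp_uv: float = 3.0,
                       subject_id: str = "S00",
                       extra_info: dict | None = None) -> tuple[Recording, GroundTruth]:
    """Project sources to electrodes, add sensor noise, build aux channels.

    Besides the task sources, ``n_background`` randomly placed deep dipoles
    with pink-noise time courses provide the spatially smooth ongoing
    activity that makes neighbouring channels correlated, as volume
    conduction does in real recordings.
    """
    sphere = sphere or SphereModel()
    if electrode_positions is None:
        electrode_positions = fibonacci_scalp_montage(n_channels, sphere)
    electrode_positions = np.asarray(electrode_positions, dtype=float)
    if electrode_positions.shape[0] != n_channels:
        n_channels = electrode_positions.shape[0]
    rng = np.random.default_rng(seed)
    n_samples = sources.shape[1]

    mixing = {reg: _mixing_matrix(source_specs, electrode_positions, sphere, reg)
              for reg in ("knee", "ankle")}
    regimes = regime_per_sample(events, n_samples)
    eeg = np.empty((n_channels, n_samples))
    # mix contiguous same-regime runs (regimes change only at trial ends)
    change = np.flatnonzero(regimes[1:] != regimes[:-1]) + 1
    bounds = np.concatenate([[0], change, [n_samples]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        eeg[:, lo:hi] = mixing[regimes[lo]] @ sources[:, lo:hi]

    A_bg = None
    if n_background > 0 and background_amp_uv > 0:
        cols = []
        for _ in range(n_background):
            u = rng.standard_normal(3)
            loc = u / np.linalg.norm(u) * rng.uniform(0.3, 0.8) * sphere.brain_radius
            topo = scalp_potential(loc, rng.standard_normal(3), electrode_positions, sphere)
            cols.append(topo / np.max(np.abs(topo)))
        A_bg = np.column_stack(cols)
        S_bg = np.empty((n_background, n_samples), dtype=np.float32)
        for j in range(n_background):
            S_bg[j] = background_amp_uv * _pink_noise(n_samples, rng)
        for lo in range(0, n_samples, 200_000):   # chunked to bound memory
            hi = min(lo + 200_000, n_samples)
            eeg[:, lo:hi] += A_bg @ S_bg[:, lo:hi]
        del S_bg
    else:
        A_bg = None

    if sensor_noise_uv > 0:
        eeg += sensor_noise_uv * rng.standard_normal(eeg.shape)
    if line_amp_uv > 0:
        tvec = np.arange(n_samples) / fs
        phase = rng.uniform(0, 2 * np.pi)
        amps = line_amp_uv * rng.uniform(0.6, 1.4, size=n_channels)
        eeg += amps[:, None] * np.sin(2 * np.pi * line_freq * tvec + phase)[None, :]
    if drift_step_uv > 0:
        eeg += np.cumsum(drift_step_uv * rng.standard_normal(eeg.shape), axis=1)

    n_aux = int(round(n_samples / fs * fs_aux))
    t_aux = np.arange(n_aux) / fs_aux
    force = np.zeros(n_aux)
    angle = np.zeros(n_aux)
    for ev in events.itertuples(index=False):
        onset, offset = ev.onset_sample / fs, ev.offset_sample / fs
        lo = max(int(onset * fs_aux), 0)
        hi = min(int(offset * fs_aux) + 1, n_aux)
        tl = t_aux[lo:hi]
        if ev.mode == "isometric":
            amp = 400.0 if ev.effort == "high" else 100.0
            # trapezoid: linear 300 ms rise and fall, plateau between
            tz = np.clip((tl - onset) / 0.3, 0, 1) * np.clip((offset - tl) / 0.3, 0, 1)
            force[lo:hi] += amp * tz
        else:
            peak = 50.0 if ev.joint == "knee" else 25.0
            if ev.direction == "extension":
                peak = -peak
            mid = (onset + offset) / 2
            tri = np.clip(1 - np.abs(tl - mid) / (offset - onset) * 2, 0, 1)
            angle[lo:hi] += peak * tri
    force += 2.0 * rng.standard_normal(n_aux)
    angle += 0.3 * rng.standard_normal(n_aux)

    labels = [f"EEG{i:03d}" for i in range(n_channels)]
    rec = Recording(eeg=eeg, fs_eeg=fs, channel_labels=labels,
                    electrode_positions=electrode_positions,
                    aux={"force": force, "angle": angle}, fs_aux=fs_aux,
                    subject_id=subject_id)
    extra_info = extra_info or {}
    gt = GroundTruth(source_specs=list(source_specs),
                     source_signals_key=[s.name for s in source_specs],
                     mixing=mixing, regime_per_sample=regimes,
                     trial_depths=extra_info.get("trial_depths", np.empty((0, 0))),
                     blink_times=extra_info.get("blink_times", np.empty(0)),
                     electrode_positions=electrode_positions,
                     background_mixing=A_bg)
    return rec, gt


# --- whole study ----------------------------------------------------------

def simulate_subject(subject_id: str = "S00", seed: int | None = 0,
                     reps: int = 20, n_channels: int = 64,
                     sphere: SphereModel | None = None,
                     source_specs=None, exercises=None,
                     subject_jitter: bool = True, **kwargs):
    """One subject's recording, events, sources and ground truth.

    Per-subject variability (when ``subject_jitter``): source locations get
    3 mm Gaussian jitter and ERD depths a 10% log-normal factor, mimicking
    anatomical and physiological differences across participants.
    Returns ``(recording, events, sources, ground_truth)``.
    """
    sphere = sphere or SphereModel()
    rng = np.random.default_rng(seed)
    specs = [replace(s) for s in (source_specs or default_sources(sphere))]
    if subject_jitter:
        dfac = float(rng.lognormal(0.0, 0.1))
        for s in specs:
            if s.role == "cortical":
                loc = s.location + rng.normal(0, 3.0, size=3)
                r_max = sphere.brain_radius * 0.98
                if np.linalg.norm(loc) > r_max:
                    loc *= r_max / np.linalg.norm(loc)
                s.location = loc
                s.erd_depth = {k: float(np.clip(v * dfac, 0.0, 0.9))
                               for k, v in s.erd_depth.items()}
    fs = kwargs.pop("fs", 512.0)
    events = make_protocol(reps=reps, fs=fs, seed=rng.integers(2 ** 31),
                           exercises=exercises)
    sources, info = simulate_sources(events, specs, fs,
                                     seed=rng.integers(2 ** 31),
                                     **{k: v for k, v in kwargs.items()
                                        if k in {"pink_db", "depth_jitter_cv", "blink_rate",
                                                 "blink_amp", "muscle_amp"}})
    rec_kwargs = {k: v for k, v in kwargs.items()
                  if k in {"fs_aux", "sensor_noise_uv", "line_amp_uv", "line_freq",
                           "drift_step_uv", "electrode_positions",
                           "n_background", "background_amp_uv"}}
    rec, gt = simulate_recording(sources, events, specs, sphere=sphere,
                                 n_channels=n_channels, fs=fs,
                                 seed=rng.integers(2 ** 31),
                                 subject_id=subject_id, extra_info=info,
                                 **rec_kwargs)
    return rec, events, sources, gt


def simulate_study(n_subjects: int = 8, seed: int | None = 0, **kwargs):
    """Generator over subjects of ``simulate_subject`` outputs."""
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(2 ** 31, size=n_subjects)
    for i in range(n_subjects):
        yield simulate_subject(subject_id=f"S{i:02d}", seed=int(subject_seeds[i]),
                               **kwargs)
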