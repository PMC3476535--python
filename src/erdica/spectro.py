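"""Time-frequency analysis of source activations.

Spectrograms use complex Morlet wavelets with a fixed-duration Gaussian
envelope: the envelope's full width (+-3 sigma) equals the 500 ms analysis
window at every frequency, so the number of cycles under the envelope grows
in proportion to frequency.  Wavelets are L2-normalized, making the
expected power of white noise equal across frequency bins, and power is
expressed in dB (10*log10).

Single-trial maps are normalized by subtracting the mean log spectrum of a
pre-trial baseline (-1000 to -500 ms), linearly time-warped so trial offset
falls at a common latency, and screened for significant deviations from
baseline with a surrogate bootstrap: the null distribution of the
trial-mean dB at each frequency is built by repeatedly drawing one random
baseline column per trial and averaging.  Values inside the two-tailed
acceptance band are set to 0 dB, the convention used for ERD displays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "Spectrogram",
    "BootstrapResult",
    "ERDStat",
    "BANDS",
    "log_freq_grid",
    "morlet_spectrogram",
    "baseline_normalize",
    "timewarp",
    "trial_spectrogram",
    "bootstrap_mask",
    "erd_statistic",
    "compare_effort_ttest",
    "compare_conditions_permutation",
]

BANDS = {"alpha": (8.0, 12.0), "beta": (12.0, 30.0)}


def log_freq_grid(n_bins: int = 220, fmin: float = 3.0, fmax: float = 150.0) -> np.ndarray:
    """Log-spaced frequency grid (default 220 bins, 3-150 Hz)."""
    if not (0 < fmin < fmax):
        raise ValueError("need 0 < fmin < fmax")
    return np.geomspace(fmin, fmax, int(n_bins))


@dataclass
class Spectrogram:
    """Time x frequency map in dB with its axes and optional annotations."""

    values: np.ndarray                  # (n_times, n_freqs), dB
    times: np.ndarray                   # seconds (relative to trial onset once aligned)
    freqs: np.ndarray                   # Hz, log-spaced
    baseline_spectrum: np.ndarray | None = None   # per-frequency mean dB of baseline
    mask: np.ndarray | None = None      # boolean (n_times, n_freqs), True = significant

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape != (self.times.size, self.freqs.size):
            raise ValueError("values must be (n_times, n_freqs)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan


def morlet_spectrogram(signal: np.ndarray, fs: float, freqs: np.ndarray | None = None,
                       window: float = 0.5, step: float = 0.025, t0: float = 0.0,
                       dtype=np.float64) -> Spectrogram:
    """Sliding-window Morlet power of a 1-D signal.

    ``window`` is the full (+-3 sigma) duration of the Gaussian envelope and
    ``step`` the slide between successive estimates.  ``t0`` is the time of
    the first sample of ``signal``; output times refer to window centres.
    Computed as a Gabor transform: framed signal times an L2-normalized
    complex-exponential/Gaussian kernel, which equals sampling the wavelet
    convolution at the step points.
    """
    x = np.asarray(signal, dtype=dtype).ravel()
    if freqs is None:
        freqs = log_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    W = int(round(window * fs))
    hop = max(int(round(step * fs)), 1)
    if x.size < W:
        raise ValueError(f"signal ({x.size} samples) shorter than the {W}-sample window")
    t = (np.arange(W) - (W - 1) / 2) / fs
    sigma = window / 6.0                      # +-3 sigma spans the window
    env = np.exp(-0.5 * (t / sigma) ** 2)
    env = env / np.sqrt(np.sum(env ** 2))     # L2 normalization of the wavelet
    phase = 2 * np.pi * freqs[:, None] * t[None, :]
    Kr = (env * np.cos(phase)).astype(dtype)
    Ki = (env * np.sin(phase)).astype(dtype)

    starts = np.arange(0, x.size - W + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, W)[starts]   # (n_frames, W)
    re = Kr @ frames.T
    im = Ki @ frames.T
    power = (re ** 2 + im ** 2).T.astype(float)                       # (n_frames, n_freqs)
    times = t0 + (starts + (W - 1) / 2) / fs
    with np.errstate(divide="ignore"):
        values = 10.0 * np.log10(np.maximum(power, 1e-300))
    return Spectrogram(values=values, times=times, freqs=freqs)


def baseline_normalize(spec: Spectrogram, baseline: tuple[float, float] = (-1.0, -0.5)
                       ) -> Spectrogram:
    """Subtract the mean baseline log spectrum per frequency.

    ``baseline`` is a half-open time interval ``[t0, t1)`` on ``spec.times``.
    """
    sel = (spec.times >= baseline[0]) & (spec.times < baseline[1])
    if not np.any(sel):
        raise ValueError(f"no spectrogram columns fall in baseline {baseline}")
    base = spec.values[sel].mean(axis=0)
    return replace(spec, values=spec.values - base[None, :], baseline_spectrum=base)


def timewarp(spec: Spectrogram, onset: float, offset: float,
             target_duration: float) -> Spectrogram:
    """Linearly warp the in-trial portion of a spectrogram to a common length.

    Columns before ``onset`` keep their latency relative to onset, columns
    within ``[onset, offset]`` are linearly resampled so the trial spans
    ``target_duration`` seconds, and columns after ``offset`` are appended
    unstretched.  Output times are relative to onset (onset -> 0).
    """
    if offset <= onset:
        raise ValueError("offset must exceed onset")
    dt = spec.dt
    pre = spec.times[spec.times < onset] - onset
    n_in = int(round(target_duration / dt))
    inside = np.arange(n_in + 1) * dt
    inside = inside[inside <= target_duration + dt * 1e-6]
    post = spec.times[spec.times > offset] - offset
    post = post[post <= spec.times.max() - offset + dt * 1e-6]
    new_times = np.concatenate([pre, inside, post + target_duration])

    # map each output latency back to an input latency
    src = np.empty_like(new_times)
    pre_n = pre.size
    in_n = inside.size
    src[:pre_n] = pre + onset
    src[pre_n:pre_n + in_n] = onset + inside * (offset - onset) / target_duration
    src[pre_n + in_n:] = post + offset
    src = np.clip(src, spec.times[0], spec.times[-1])

    idx = np.searchsorted(spec.times, src, side="right") - 1
    idx = np.clip(idx, 0, spec.times.size - 2)
    w = (src - spec.times[idx]) / dt
    values = (1 - w)[:, None] * spec.values[idx] + w[:, None] * spec.values[idx + 1]
    return replace(spec, values=values, times=new_times, mask=None)


def trial_spectrogram(signal: np.ndarray, fs: float, onset_s: float, offset_s: float,
                      target_duration: float, freqs: np.ndarray | None = None,
                      pre: float = 1.0, post: float = 1.0,
                      baseline: tuple[float, float] = (-1.0, -0.5),
                      window: float = 0.5, step: float = 0.025,
                      dtype=np.float64) -> Spectrogram:
    """Normalized, time-warped spectrogram of one trial.

    ``signal`` is the full continuous activation; ``onset_s``/``offset_s``
    are trial bounds in seconds on the same clock.  The analysed segment
    spans ``[onset - pre - window/2, offset + post + window/2]``.
    """
    lo = int(round((onset_s - pre - window / 2) * fs))
    hi = int(round((offset_s + post + window / 2) * fs)) + 1
    if lo < 0 or hi > signal.size:
        raise ValueError("trial (plus padding) extends beyond the recording")
    raw = morlet_spectrogram(signal[lo:hi], fs, freqs=freqs, window=window,
                             step=step, t0=lo / fs - onset_s, dtype=dtype)
    norm = baseline_normalize(raw, baseline=baseline)
    warped = timewarp(norm, onset=0.0, offset=offset_s - onset_s,
                      target_duration=target_duration)
    # regrid onto the canonical latency axis so every trial has the same
    # shape regardless of sample-rounding at the segment edges
    n_pre = int(round(pre / step))
    n_in = int(round(target_duration / step))
    n_post = int(round(post / step))
    tgrid = np.concatenate([
        np.arange(-n_pre, 0) * step,
        np.arange(0, n_in + 1) * step,
        n_in * step + np.arange(1, n_post + 1) * step,
    ])
    src = np.clip(tgrid, warped.times[0], warped.times[-1])
    idx = np.clip(np.searchsorted(warped.times, src, side="right") - 1,
                  0, warped.times.size - 2)
    w = np.clip((src - warped.times[idx]) / warped.dt, 0.0, 1.0)
    values = (1 - w)[:, None] * warped.values[idx] + w[:, None] * warped.values[idx + 1]
    return replace(warped, values=values, times=tgrid)


def null_pool_columns(times: np.ndarray, baseline: tuple[float, float] = (-1.0, -0.5),
                      window: float = 0.5, spacing: float | None = None) -> np.ndarray:
    """Column indices usable as surrogate-null draws for :func:`bootstrap_mask`.

    The pool contains pre-trial (pause) columns whose analysis windows do
    not overlap the normalization baseline — otherwise the surrogate
    inherits the negative correlation with the subtracted baseline mean and
    under-estimates the null spread — thinned to one column per
    ``spacing`` seconds (default ``window/2``, about the decorrelation
    length of overlapping spectral estimates) so the pool values are
    mutually near-independent.
    """
    times = np.asarray(times, dtype=float)
    spacing = window / 2 if spacing is None else spacing
    limit = baseline[0] - window / 2
    idx = np.flatnonzero(times <= limit)
    if idx.size == 0:
        raise ValueError(
            f"no columns before {limit:.2f} s; extend the pre-trial interval")
    step = max(int(round(spacing / (times[1] - times[0]))), 1)
    return idx[::-1][::step][::-1]      # thin from the baseline edge backwards


@dataclass
class BootstrapResult:
    grand: np.ndarray         # (n_times, n_freqs) trial-mean dB
    mask: np.ndarray          # boolean, True = significant vs baseline null
    thresholded: np.ndarray   # grand with non-significant cells set to 0 dB
    lower: np.ndarray         # (n_freqs,) acceptance band
    upper: np.ndarray


def _stack_trials(trial_specs):
    if isinstance(trial_specs, np.ndarray):
        return trial_specs
    return np.stack([s.values if isinstance(s, Spectrogram) else np.asarray(s)
                     for s in trial_specs])


def bootstrap_mask(trial_specs, baseline_cols, alpha: float = 0.05,
                   n_boot: int = 200, seed: int | None = 0) -> BootstrapResult:
    """Surrogate-bootstrap significance mask for a set of trial spectrograms.

    For every frequency the null distribution of the trial-mean dB is built
    by drawing, ``n_boot`` times, one random baseline column per trial and
    averaging across trials.  Grand-average values outside the two-tailed
    ``alpha`` acceptance band are significant; the rest are zeroed.
    """
    arr = _stack_trials(trial_specs)
    if arr.ndim != 3:
        raise ValueError("trial_specs must stack to (n_trials, n_times, n_freqs)")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_boot < 50:
        warnings.warn(f"n_boot={n_boot} gives unstable percentile estimates",
                      stacklevel=2)
    baseline_cols = np.asarray(baseline_cols, dtype=int)
    if baseline_cols.size == 0:
        raise ValueError("baseline_cols is empty")
    n_trials = arr.shape[0]
    rng = np.random.default_rng(seed)
    draw = baseline_cols[rng.integers(0, baseline_cols.size, size=(n_boot, n_trials))]
    values = arr[np.arange(n_trials)[None, :], draw, :]          # (n_boot, n_trials, F)
    m = baseline_cols.size
    if m > 1:
        # finite-pool correction: resampling m values per trial understates
        # the null spread by (1 - 1/m); rescale deviations from the pool mean
        pool_mean = arr[:, baseline_cols, :].mean(axis=1)        # (n_trials, F)
        values = pool_mean[None] + (values - pool_mean[None]) * np.sqrt(m / (m - 1))
    surrogate = values.mean(axis=1)                              # (n_boot, F)
    # outward-rounded order statistics: at finite n_boot the interpolated
    # percentile sits inside the true tail, which would be anti-conservative
    lower = np.quantile(surrogate, alpha / 2, axis=0, method="lower")
    upper = np.quantile(surrogate, 1 - alpha / 2, axis=0, method="higher")
    grand = arr.mean(axis=0)
    mask = (grand < lower[None, :]) | (grand > upper[None, :])
    return BootstrapResult(grand=grand, mask=mask,
                           thresholded=np.where(mask, grand, 0.0),
                           lower=lower, upper=upper)


@dataclass
class ERDStat:
    """Mean significant dB change in one band over the in-trial interval."""

    band: str
    mean_db: float
    n_points: int


def erd_statistic(grand: np.ndarray, mask: np.ndarray, times: np.ndarray,
                  freqs: np.ndarray, band, interval: tuple[float, float]) -> ERDStat:
    """Mean dB over mask-true points with frequency in ``band`` and time in
    ``interval`` (typically onset to warped offset).

    ``band`` is a name from :data:`BANDS` or an explicit ``(lo, hi)`` pair.
    An empty selection is flagged with ``mean_db = nan`` and ``n_points = 0``.
    """
    name = band if isinstance(band, str) else f"{band[0]:g}-{band[1]:g}Hz"
    lo, hi = BANDS[band] if isinstance(band, str) else band
    sel = (mask
           & ((freqs >= lo) & (freqs <= hi))[None, :]
           & ((times >= interval[0]) & (times <= interval[1]))[:, None])
    n = int(sel.sum())
    mean = float(grand[sel].mean()) if n else float("nan")
    return ERDStat(band=name, mean_db=mean, n_points=n)


def compare_effort_ttest(erd_high: np.ndarray, erd_low: np.ndarray) -> tuple[float, float]:
    """Paired two-sided t-test of per-subject ERD depth (high vs low effort).

    A zero-variance paired difference is handled as the analytic limit:
    t = 0, p = 1 for a zero mean difference, |t| = inf, p = 0 otherwise.
    """
    d = np.asarray(erd_high, dtype=float) - np.asarray(erd_low, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two paired observations")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.isclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(erd_high, erd_low)
    return float(t), float(p)


def compare_conditions_permutation(specs_a, specs_b, alpha: float = 0.05,
                                   n_perm: int = 500, seed: int | None = 0):
    """Pointwise permutation test of the mean spectrogram difference A - B.

    Condition labels are permuted across trials; each (time, frequency)
    point is flagged where the observed difference falls outside the
    two-tailed ``alpha`` band of the permutation distribution.  If the
    number of label assignments is no larger than ``n_perm`` the exact
    enumeration is used instead of random permutations.

    Returns ``(difference_map, mask)``.
    """
    from itertools import combinations
    from math import comb

    A = _stack_trials(specs_a)
    B = _stack_trials(specs_b)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("condition spectrograms have mismatched grids")
    nA, nB = A.shape[0], B.shape[0]
    pooled = np.concatenate([A, B], axis=0)
    flat = pooled.reshape(nA + nB, -1)
    total = flat.sum(axis=0)
    obs = A.mean(axis=0) - B.mean(axis=0)

    def diff_from(idx_a: np.ndarray) -> np.ndarray:
        sum_a = flat[idx_a].sum(axis=0)
        return sum_a / nA - (total - sum_a) / nB

    if comb(nA + nB, nA) <= n_perm:
        diffs = np.stack([diff_from(np.array(c))
                          for c in combinations(range(nA + nB), nA)])
    else:
        rng = np.random.default_rng(seed)
        diffs = np.stack([diff_from(rng.permutation(nA + nB)[:nA])
                          for _ in range(n_perm)])
    lower = np.quantile(diffs, alpha / 2, axis=0).reshape(obs.shape)
    upper = np.quantile(diffs, 1 - alpha / 2, axis=0).reshape(obs.shape)
    mask = (obs < lower) | (obs > upper)
    return obs, mask
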