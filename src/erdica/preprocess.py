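"""Channel-domain preprocessing: filtering, quality rejection, referencing,
and mechanical trial-bound refinement.

Channel rejection applies three rules in a fixed order, each computed once
on the survivors of the previous rule:

1. sample standard deviation >= 1000 uV (gross artifact / disconnected);
2. kurtosis more than 3 standard deviations above the across-channel mean
   kurtosis (sporadic pops);
3. channels that are uncorrelated (max |r| <= 0.4 against their 4 nearest
   spatial neighbours) in more than 0.1% of 1 s windows.

Trial bounds are refined from the mechanical channels: load-cell force for
isometric trials, absolute goniometer deviation for isotonic ones, with a
threshold at baseline + 10% of the peak-to-baseline range and 2%
hysteresis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .io import Recording

__all__ = ["RejectionReport", "highpass", "reject_channels",
           "rereference_average", "detect_trial_bounds", "preprocess_recording"]

logger = logging.getLogger(__name__)


@dataclass
class RejectionReport:
    """Per-channel verdicts of the three quality rules."""

    verdicts: dict               # label -> kept | rejected_std | rejected_kurtosis | rejected_correlation
    thresholds: dict
    retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": list(self.verdicts),
                             "verdict": list(self.verdicts.values())})


def highpass(recording: Recording, cutoff: float = 1.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass (forward-backward, 2x order roll-off)."""
    if cutoff >= recording.fs_eeg / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff, btype="highpass", fs=recording.fs_eeg,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, recording.eeg, axis=1)
    return recording.copy_with(eeg=filtered)


def reject_channels(recording: Recording, std_limit_uv: float = 1000.0,
                    kurtosis_sd: float = 3.0, corr_threshold: float = 0.4,
                    corr_window_s: float = 1.0, corr_max_fraction: float = 0.001,
                    n_neighbors: int = 4) -> tuple[Recording, RejectionReport]:
    """Apply the three channel-quality rules in order; returns survivors.

    Raises if fewer than 8 channels survive (downstream ICA needs a
    minimal montage).
    """
    eeg = recording.eeg
    labels = list(recording.channel_labels)
    if len(labels) < 8:
        raise ValueError("channel rejection requires at least 8 channels")
    verdicts = {lb: "kept" for lb in labels}

    # rule 1: gross amplitude
    stds = eeg.std(axis=1)
    for i in np.flatnonzero(stds >= std_limit_uv):
        verdicts[labels[i]] = "rejected_std"
    alive = np.flatnonzero(stds < std_limit_uv)

    # rule 2: kurtosis outliers among rule-1 survivors (single pass)
    kurt = stats.kurtosis(eeg[alive], axis=1, fisher=True)
    k_mean = kurt.mean()
    k_sd = kurt.std(ddof=1) if alive.size > 1 else 0.0
    if alive.size > 1 and k_sd > 0:
        bad = kurt > k_mean + kurtosis_sd * k_sd
        for i in alive[bad]:
            verdicts[labels[i]] = "rejected_kurtosis"
        alive = alive[~bad]

    # rule 3: windowed neighbour correlation among rule-2 survivors
    win = int(round(corr_window_s * recording.fs_eeg))
    n_win = eeg.shape[1] // win
    if n_win >= 1 and alive.size > n_neighbors:
        pos = recording.electrode_positions[alive]
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nbrs = np.argsort(d, axis=1)[:, :n_neighbors]
        X = eeg[alive, : n_win * win].reshape(alive.size, n_win, win)
        Xc = X - X.mean(axis=2, keepdims=True)
        denom = np.sqrt((Xc ** 2).sum(axis=2))
        uncorr_frac = np.empty(alive.size)
        for a in range(alive.size):
            nb = nbrs[a]
            r = (Xc[a][None] * Xc[nb]).sum(axis=2) / (denom[a][None] * denom[nb] + 1e-30)
            max_abs_r = np.abs(r).max(axis=0)          # best neighbour per window
            uncorr_frac[a] = np.mean(max_abs_r <= corr_threshold)
        bad = uncorr_frac > corr_max_fraction
        for i in alive[bad]:
            verdicts[labels[i]] = "rejected_correlation"
        alive = alive[~bad]

    if alive.size < 8:
        raise ValueError(f"only {alive.size} channels survive rejection; "
                         "need at least 8 for ICA")
    report = RejectionReport(
        verdicts=verdicts,
        thresholds={"std_limit_uv": std_limit_uv, "kurtosis_sd": kurtosis_sd,
                    "corr_threshold": corr_threshold,
                    "corr_max_fraction": corr_max_fraction,
                    "corr_window_s": corr_window_s, "n_neighbors": n_neighbors},
        retained=int(alive.size),
    )
    kept = recording.copy_with(eeg=eeg[alive],
                               channel_labels=[labels[i] for i in alive],
                               electrode_positions=recording.electrode_positions[alive])
    return kept, report


def rereference_average(recording: Recording) -> Recording:
    """Subtract the across-channel mean at every sample."""
    eeg = recording.eeg - recording.eeg.mean(axis=0, keepdims=True)
    return recording.copy_with(eeg=eeg)


def _refine_one(sig: np.ndarray, fs_aux: float, nominal_on: float, nominal_off: float,
                rel_threshold: float, hysteresis: float):
    """Threshold-crossing bounds of one trial on one mechanical signal."""
    i_on = int(nominal_on * fs_aux)
    i_off = int(nominal_off * fs_aux)
    base_lo = max(i_on - int(fs_aux), 0)
    if base_lo >= i_on:
        return None
    baseline = np.median(sig[base_lo:i_on])
    lo = max(i_on - int(2 * fs_aux), 0)
    hi = min(i_off + int(2 * fs_aux), sig.size)
    seg = sig[lo:hi]
    peak = seg.max()
    rng = peak - baseline
    if rng <= 0:
        return None
    thr_hi = baseline + rel_threshold * rng
    thr_lo = baseline + (rel_threshold - hysteresis) * rng
    above = seg > thr_hi
    if not above.any():
        return None
    first = int(np.argmax(above))
    last = int(seg.size - 1 - np.argmax(above[::-1]))
    # hysteresis: walk outwards while the signal stays above the lower threshold
    while first > 0 and seg[first - 1] > thr_lo:
        first -= 1
    while last < seg.size - 1 and seg[last + 1] > thr_lo:
        last += 1
    return (lo + first) / fs_aux, (lo + last + 1) / fs_aux


def detect_trial_bounds(recording: Recording, events: pd.DataFrame,
                        rel_threshold: float = 0.10,
                        hysteresis: float = 0.02) -> pd.DataFrame:
    """Refine nominal trial bounds from the mechanical channels.

    Isometric trials are timed on load-cell force, isotonic trials on the
    absolute deviation of the goniometer angle from its pre-trial level.
    Trials with no threshold crossing keep their nominal bounds (with a
    logged warning).  Returns a copy of ``events`` with refined samples (in
    EEG sample units).
    """
    fs, fs_aux = recording.fs_eeg, recording.fs_aux
    out = events.copy()
    for idx, ev in enumerate(events.itertuples(index=False)):
        nominal_on = ev.onset_sample / fs
        nominal_off = ev.offset_sample / fs
        if ev.mode == "isometric":
            sig = recording.aux.get("force")
        else:
            angle = recording.aux.get("angle")
            if angle is not None:
                i_on = int(nominal_on * fs_aux)
                ref = np.median(angle[max(i_on - int(fs_aux), 0):i_on]) if i_on else 0.0
                sig = np.abs(angle - ref)
            else:
                sig = None
        res = _refine_one(sig, fs_aux, nominal_on, nominal_off,
                          rel_threshold, hysteresis) if sig is not None else None
        if res is None:
            logger.warning("trial %d (%s): no mechanical crossing, keeping "
                           "nominal bounds", idx, ev.mode)
            continue
        on_s, off_s = res
        out.iat[idx, out.columns.get_loc("onset_sample")] = int(round(on_s * fs))
        out.iat[idx, out.columns.get_loc("offset_sample")] = int(round(off_s * fs))
    return out


def preprocess_recording(recording: Recording, events: pd.DataFrame,
                         cutoff: float = 1.0, refine_bounds: bool = True,
                         **reject_kwargs):
    """Full channel-domain chain: high-pass, reject, re-reference, refine.

    Returns ``(recording, events, report)``.
    """
    rec = highpass(recording, cutoff=cutoff)
    rec, report = reject_channels(rec, **reject_kwargs)
    rec = rereference_average(rec)
    if refine_bounds and len(events):
        events = detect_trial_bounds(rec, events)
    return rec, events, report
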