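"""Data model and on-disk formats.

A :class:`Recording` bundles the EEG matrix (microvolts, channels x
samples), the electrode geometry, and the auxiliary mechanical channels
(load-cell force in newtons, joint angle in degrees) that run on their own
clock.  Trial events live in a plain table with one row per exercise
repetition and four factors: joint (knee/ankle), mode (isometric/isotonic),
direction (flexion/extension) and effort (high/low).

On disk a recording is a small family of text-friendly files sharing a stem:

    <stem>.edf            EEG, 16-bit EDF at fs_eeg
    <stem>_aux.edf        auxiliary channels at fs_aux (separate file so
                          each rate group round-trips exactly)
    <stem>.events.tsv     trial events (six columns)
    <stem>.positions.tsv  electrode label, x, y, z (mm, head frame)
    <stem>.meta.json      subject id, rates, exact sample counts

Sample indices are 0-based and intervals half-open ``[onset, offset)``.
Reading goes through MNE's EDF reader; writing uses the package's own
16-bit EDF writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._edf import write_edf

__all__ = ["Recording", "validate_events", "read_recording", "write_recording",
           "read_events", "write_events", "trial_sample_mask", "EVENT_COLUMNS"]

EVENT_COLUMNS = ["onset_sample", "offset_sample", "joint", "mode", "direction", "effort"]
_FACTOR_LEVELS = {
    "joint": {"knee", "ankle"},
    "mode": {"isometric", "isotonic"},
    "direction": {"flexion", "extension"},
    "effort": {"high", "low"},
}
AUX_PREFIX = "AUX"


@dataclass
class Recording:
    """Multichannel EEG plus auxiliary mechanical signals.

    ``eeg`` is (n_channels, n_samples) in microvolts.  ``electrode_positions``
    is (n_channels, 3) in mm, head frame (origin at the sphere centre, +X
    right, +Y anterior, +Z superior); electrodes must lie on a common scalp
    sphere to within 1% radial tolerance.  ``aux`` maps names like ``force``
    and ``angle`` to 1-D arrays sampled at ``fs_aux``.
    """

    eeg: np.ndarray
    fs_eeg: float
    channel_labels: list
    electrode_positions: np.ndarray
    aux: dict = field(default_factory=dict)
    fs_aux: float = 1000.0
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg))
        self.electrode_positions = np.asarray(self.electrode_positions, dtype=float)
        if self.fs_eeg <= 0 or self.fs_aux <= 0:
            raise ValueError("sampling rates must be positive")
        n = self.eeg.shape[0]
        if len(self.channel_labels) != n or self.electrode_positions.shape != (n, 3):
            raise ValueError("channel_labels and electrode_positions must match eeg rows")
        radii = np.linalg.norm(self.electrode_positions, axis=1)
        if radii.size and np.any(np.abs(radii - np.median(radii)) > 0.01 * np.median(radii)):
            raise ValueError("electrodes must lie on the scalp sphere (1% tolerance)")

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs_eeg

    def copy_with(self, eeg=None, channel_labels=None, electrode_positions=None) -> "Recording":
        return Recording(
            eeg=self.eeg if eeg is None else eeg,
            fs_eeg=self.fs_eeg,
            channel_labels=list(self.channel_labels if channel_labels is None else channel_labels),
            electrode_positions=(self.electrode_positions if electrode_positions is None
                                 else electrode_positions),
            aux=dict(self.aux),
            fs_aux=self.fs_aux,
            subject_id=self.subject_id,
        )


def validate_events(events: pd.DataFrame, n_samples: int | None = None,
                    protocol_strict: bool = True) -> pd.DataFrame:
    """Validate a trial-event table, returning it with normalized dtypes.

    Raises on missing columns, unknown factor levels, non-positive
    durations, unsorted or overlapping trials, and (when
    ``protocol_strict``) on isotonic knee flexion rows, a combination the
    exercise apparatus cannot produce.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    ev = events[EVENT_COLUMNS].copy()
    ev["onset_sample"] = ev["onset_sample"].astype(int)
    ev["offset_sample"] = ev["offset_sample"].astype(int)
    for col, levels in _FACTOR_LEVELS.items():
        bad = set(ev[col].unique()) - levels
        if bad:
            raise ValueError(f"unknown {col} levels: {sorted(bad)}")
    bad_rows = ev.index[ev["offset_sample"] <= ev["onset_sample"]]
    if len(bad_rows):
        raise ValueError(f"offset_sample <= onset_sample at rows {list(bad_rows[:5])}")
    onsets = ev["onset_sample"].to_numpy()
    offsets = ev["offset_sample"].to_numpy()
    if np.any(np.diff(onsets) < 0):
        raise ValueError("events must be sorted by onset_sample")
    if np.any(onsets[1:] < offsets[:-1]):
        raise ValueError("trials must not overlap")
    if n_samples is not None and len(ev) and offsets.max() > n_samples:
        raise ValueError("events extend past the end of the recording")
    if protocol_strict:
        ikf = ev[(ev.joint == "knee") & (ev["mode"] == "isotonic")
                 & (ev.direction == "flexion")]
        if len(ikf):
            raise ValueError(
                f"isotonic knee flexion is not part of the protocol (rows {list(ikf.index[:5])})")
    return ev


def trial_sample_mask(events: pd.DataFrame, n_samples: int) -> np.ndarray:
    """Boolean mask of samples lying inside any trial interval."""
    mask = np.zeros(int(n_samples), dtype=bool)
    for ev in events.itertuples(index=False):
        mask[int(ev.onset_sample):int(ev.offset_sample)] = True
    return mask


def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events).to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path, sep="\t"))


def _paths(stem: Path) -> dict:
    return {
        "eeg": stem.with_suffix(".edf"),
        "aux": stem.parent / (stem.name + "_aux.edf"),
        "events": stem.parent / (stem.name + ".events.tsv"),
        "positions": stem.parent / (stem.name + ".positions.tsv"),
        "meta": stem.parent / (stem.name + ".meta.json"),
    }


def write_recording(recording: Recording, events: pd.DataFrame, out_stem) -> dict:
    """Write a recording family (EDF + TSV + JSON) under ``out_stem``.

    Returns the mapping of artefact names to paths.
    """
    stem = Path(out_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    p = _paths(stem)
    validate_events(events, n_samples=recording.n_samples)

    write_edf(p["eeg"], recording.eeg, recording.fs_eeg,
              recording.channel_labels, phys_dim="uV",
              patient_id=recording.subject_id)
    aux_names = sorted(recording.aux)
    if aux_names:
        aux_units = {"force": "N", "angle": "deg"}
        aux_data = np.vstack([recording.aux[k] for k in aux_names])
        write_edf(p["aux"], aux_data, recording.fs_aux,
                  [f"{AUX_PREFIX}_{k}" for k in aux_names],
                  phys_dim=[aux_units.get(k, "au") for k in aux_names],
                  patient_id=recording.subject_id)
    write_events(events, p["events"])
    pos = pd.DataFrame(recording.electrode_positions, columns=["x", "y", "z"])
    pos.insert(0, "label", recording.channel_labels)
    pos.to_csv(p["positions"], sep="\t", index=False)
    meta = {
        "subject_id": recording.subject_id,
        "fs_eeg": recording.fs_eeg,
        "fs_aux": recording.fs_aux,
        "n_samples_eeg": int(recording.n_samples),
        "n_samples_aux": {k: int(len(v)) for k, v in recording.aux.items()},
    }
    p["meta"].write_text(json.dumps(meta, indent=1))
    return p


def read_recording(signal_path, events_path=None) -> tuple[Recording, pd.DataFrame]:
    """Read a recording family written by :func:`write_recording`.

    ``signal_path`` is the EEG EDF (or the shared stem); the events,
    positions, aux and meta sidecars are located by naming convention, or
    the events table can be pointed at explicitly.
    """
    import mne

    stem = Path(signal_path)
    if stem.suffix == ".edf":
        stem = stem.with_suffix("")
    p = _paths(stem)
    if not p["eeg"].exists():
        raise FileNotFoundError(p["eeg"])
    meta = json.loads(p["meta"].read_text()) if p["meta"].exists() else {}

    raw = mne.io.read_raw_edf(p["eeg"], preload=True, verbose="error")
    eeg = raw.get_data() * 1e6            # MNE reads uV-dimensioned data in volts
    n_eeg = meta.get("n_samples_eeg", eeg.shape[1])
    eeg = eeg[:, :n_eeg]
    labels = list(raw.ch_names)

    pos_tab = pd.read_csv(p["positions"], sep="\t")
    pos_map = {r.label: (r.x, r.y, r.z) for r in pos_tab.itertuples(index=False)}
    missing = [lb for lb in labels if lb not in pos_map]
    if missing:
        raise ValueError(f"channels missing from the position table: {missing}")
    positions = np.array([pos_map[lb] for lb in labels])

    aux: dict = {}
    fs_aux = meta.get("fs_aux", 1000.0)
    if p["aux"].exists():
        raw_aux = mne.io.read_raw_edf(p["aux"], preload=True, verbose="error")
        fs_aux = float(raw_aux.info["sfreq"])
        counts = meta.get("n_samples_aux", {})
        for ch in raw_aux.ch_names:
            name = ch.removeprefix(f"{AUX_PREFIX}_")
            sig = raw_aux.get_data(picks=[ch])[0]
            aux[name] = sig[: counts.get(name, sig.size)]

    recording = Recording(eeg=eeg, fs_eeg=float(raw.info["sfreq"]),
                          channel_labels=labels, electrode_positions=positions,
                          aux=aux, fs_aux=fs_aux,
                          subject_id=meta.get("subject_id", "S00"))
    ev_path = Path(events_path) if events_path is not None else p["events"]
    events = read_events(ev_path) if ev_path.exists() else pd.DataFrame(columns=EVENT_COLUMNS)
    if len(events):
        validate_events(events, n_samples=recording.n_samples)
    return recording, events
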