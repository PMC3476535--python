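"""Minimal EDF writer (16-bit European Data Format, one file per rate group).

Only writing lives here: reading goes through MNE's EDF reader, which also
serves as an independent check on this writer in the round-trip tests.
Records are fixed at 1 s; the final record is padded by repeating the last
sample, and the true sample count is recorded in a JSON sidecar by the
caller.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

__all__ = ["write_edf"]


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, labels, phys_dim: str = "uV",
              patient_id: str = "X", recording_id: str = "erdica") -> None:
    """Write ``data`` (n_channels, n_samples) to an EDF file at ``path``.

    All channels share one sampling rate; ``phys_dim`` may be a single
    dimension string or one per channel.  Physical min/max are set per
    channel from the data, so quantization error is at most
    (max-min)/65534 per channel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.isfinite(data).all():
        raise ValueError("EDF data must be finite")
    n_ch, n_samp = data.shape
    labels = list(labels)
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")
    dims = [phys_dim] * n_ch if isinstance(phys_dim, str) else list(phys_dim)
    if len(dims) != n_ch:
        raise ValueError("one physical dimension per channel required")
    fs = int(round(fs))
    spr = fs                       # samples per 1-s record
    n_rec = max(int(np.ceil(n_samp / spr)), 1)

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(lb, 16) for lb in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(d, 8) for d in dims),
        b"".join(_field(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(_field(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(_field(str(dmin), 8) for _ in labels),
        b"".join(_field(str(dmax), 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(str(spr), 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])

    # physical min/max written with %.6g may round; recompute the exact
    # values the reader will parse so digital codes stay consistent
    pmin_w = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_w = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (pmax_w - pmin_w) / (dmax - dmin)
    offset = pmin_w - dmin * scale

    padded = np.empty((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    if n_rec * spr > n_samp:
        padded[:, n_samp:] = data[:, -1:]
    digital = np.clip(np.round((padded - offset[:, None]) / scale[:, None]),
                      dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
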