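"""Rendering of masked spectrograms (ERD display convention)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_masked_spectrogram"]


def plot_masked_spectrogram(values, times, freqs, onset: float = 0.0,
                            offset: float | None = None, ax=None,
                            vlim: float | None = None, title: str = ""):
    """Plot a (time x frequency) dB map with onset/offset markers.

    Non-significant cells are expected to already be 0 dB (green in the
    diverging colormap).  Frequency axis is logarithmic.
    """
    import matplotlib.pyplot as plt

    values = np.asarray(values)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if vlim is None:
        vlim = max(float(np.abs(values).max()), 1e-3)
    mesh = ax.pcolormesh(times, freqs, values.T, cmap="RdYlGn_r",
                         vmin=-vlim, vmax=vlim, shading="nearest")
    ax.set_yscale("log")
    ax.axvline(onset, color="k", lw=1)
    if offset is not None:
        ax.axvline(offset, color="k", lw=1)
    ax.set_xlabel("time relative to onset (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(mesh, ax=ax, label="dB vs baseline")
    return ax
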