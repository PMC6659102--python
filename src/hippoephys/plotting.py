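"""Display helpers (matplotlib is an optional dependency)."""

from __future__ import annotations

import numpy as np

from .emd import IMFSet
from .spectral import PSDEstimate
from .spikefield import STAResult


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install hippoephys[plot])") from exc
    return plt


def plot_psd(psd: PSDEstimate, f_max: float = 150.0, ax=None, **kwargs):
    """Welch PSD on a log power axis up to ``f_max`` Hz."""
    plt = _plt()
    ax = ax or plt.gca()
    m = psd.freqs <= f_max
    ax.semilogy(psd.freqs[m], psd.density[m], **kwargs)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (mV$^2$/Hz)")
    return ax


def plot_sta(sta: STAResult, ax=None, **kwargs):
    """Spike-triggered average with the +-250 ms summary windows shaded."""
    plt = _plt()
    ax = ax or plt.gca()
    ax.plot(sta.lags, sta.mean_lfp, **kwargs)
    ax.axvspan(-0.25, 0, alpha=0.1, color="tab:blue")
    ax.axvspan(0, 0.25, alpha=0.1, color="tab:orange")
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("LFP (mV)")
    return ax


def plot_imfs(imfset: IMFSet, max_imfs: int = 8, axes=None):
    """Stacked IMFs plus residual, labelled with mean frequencies."""
    plt = _plt()
    k = min(imfset.n_imfs, max_imfs)
    if axes is None:
        _, axes = plt.subplots(k + 1, 1, sharex=True, figsize=(8, 1.2 * (k + 1)))
    t = np.arange(imfset.residual.size) / imfset.sampling_rate
    for i in range(k):
        axes[i].plot(t, imfset.imfs[i], lw=0.6)
        axes[i].set_ylabel(f"{imfset.mean_inst_freq[i]:.3g} Hz", fontsize=7)
    axes[k].plot(t, imfset.residual, lw=0.6, color="gray")
    axes[k].set_ylabel("res", fontsize=7)
    axes[k].set_xlabel("time (s)")
    return axes
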