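"""Channel-panel visualization of 7-channel stacks."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import CHANNEL_NAMES

__all__ = ["plot_channel_panels"]


def plot_channel_panels(stack_data: np.ndarray, path: str, title: str = "") -> None:
    """Write a 7-panel PNG (four orientation channels, then R, G, B)."""
    data = np.asarray(stack_data)
    if data.ndim != 3 or data.shape[0] != len(CHANNEL_NAMES):
        raise ValueError("expected a (7, H, W) stack")
    fig, axes = plt.subplots(1, 7, figsize=(14, 2.4))
    vmax = float(np.abs(data).max()) or 1.0
    for ax, name, chan in zip(axes, CHANNEL_NAMES, data):
        ax.imshow(chan, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_title(name, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    if title:
        fig.suptitle(title, fontsize=10)
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    fig.savefig(path, dpi=100, metadata={"Software": "fragface"})
    plt.close(fig)
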