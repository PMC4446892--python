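"""Spectrogram contact sheets for visual review of clusters and ties."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .segmentation import VocalElement
from .signal_io import spectrogram

__all__ = ["contact_sheet"]


def contact_sheet(
    elements: list[VocalElement],
    path: str | Path,
    title: str = "",
    max_elements: int = 16,
    window_length: float = 0.002,
    step: float = 0.001,
) -> Path:
    """Write a grid of element spectrograms to a PNG for human review."""
    elements = elements[:max_elements]
    n = len(elements)
    if n == 0:
        raise ValueError("no elements to plot")
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(2.2 * cols, 1.8 * rows), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, e in zip(axes.ravel(), elements):
        win = min(window_length, e.audio.duration / 2)
        s = spectrogram(e.audio, win, min(step, win))
        ax.imshow(
            np.log(s.magnitudes.T + 1e-9),
            origin="lower",
            aspect="auto",
            cmap="magma",
            extent=[0, e.duration * 1000, s.freq_axis[0] / 1000, s.freq_axis[-1] / 1000],
        )
        ax.set_title(e.element_id, fontsize=6)
        ax.axis("on")
        ax.tick_params(labelsize=5)
    if title:
        fig.suptitle(title, fontsize=9)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
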