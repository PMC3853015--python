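"""Optional figure rendering (time-frequency maps and scalp topographies).

Matplotlib is imported lazily with the Agg backend so headless CSV-only runs
never touch a display.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from micsp.io_preprocess import ChannelLayout
from micsp.spectral_features import ERSPMap


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_ersp_map(m: ERSPMap, path: str | Path, title: str = "", vlim: float = 6.0) -> None:
    """Render an ERSP map (time x frequency, dB) to `path`."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    mesh = ax.pcolormesh(m.times, m.freqs, m.values, cmap="RdBu_r", vmin=-vlim, vmax=vlim, shading="auto")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="dB")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_topography(
    values: dict[str, float], layout: ChannelLayout, path: str | Path, title: str = ""
) -> None:
    """Render per-electrode scalar values as a colored scalp scatter."""
    plt = _pyplot()
    names = list(values)
    pos = layout.coords(names)
    v = np.array([values[n] for n in names])
    fig, ax = plt.subplots(figsize=(4, 4))
    lim = max(abs(v.min()), abs(v.max())) or 1.0
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=v, s=160, cmap="RdBu_r", vmin=-lim, vmax=lim,
                    edgecolors="k", linewidths=0.4)
    for (x, y), name in zip(pos, names):
        ax.annotate(name, (x, y), fontsize=4, ha="center", va="center")
    head = plt.Circle((0, 0), 1.0, fill=False, color="k")
    ax.add_patch(head)
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
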