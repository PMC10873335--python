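"""Figure output: line-profile plots and subtraction images to PNG."""

from __future__ import annotations

import numpy as np

from .metrics import line_profile

__all__ = ["save_profile_plot", "save_subtraction_image"]


def save_profile_plot(path, images: dict, orientation: str, index: int,
                      title: str | None = None) -> None:
    """Overlay HU line profiles of several named images at one row/column."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, image in images.items():
        prof = line_profile(np.asarray(image), orientation, index)
        ax.plot(prof["pixel"], prof["hu"], label=name, linewidth=1.0)
    ax.set_xlabel("pixel")
    ax.set_ylabel("CT value (HU)")
    ax.legend(loc="best", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_subtraction_image(path, x, y, limit: float = 200.0) -> None:
    """Signed difference image (X - Y) on a symmetric HU scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(diff, cmap="seismic", vmin=-limit, vmax=limit)
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, shrink=0.8, label="HU difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
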