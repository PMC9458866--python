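"""Convenience plots (no 3-D rendering; orthoslices only)."""

from __future__ import annotations

import numpy as np

from .localize import FunctionalTomogram


def save_orthoslices(path, tomogram: FunctionalTomogram) -> None:
    """PNG with sagittal/coronal/axial slices through the energy maximum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vol = tomogram.volume
    peak = np.unravel_index(np.argmax(vol), vol.shape)
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.5))
    planes = [
        (vol[peak[0], :, :].T, "sagittal (x fixed)", "y", "z"),
        (vol[:, peak[1], :].T, "coronal (y fixed)", "x", "z"),
        (vol[:, :, peak[2]].T, "axial (z fixed)", "x", "y"),
    ]
    for ax, (img, title, xl, yl) in zip(axes, planes):
        im = ax.imshow(img, origin="lower", cmap="inferno")
        ax.set_title(title, fontsize=9)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle("functional tomogram energy (T$^2$)", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
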