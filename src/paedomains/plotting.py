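"""PAE heatmap with optional domain-boundary overlay.

Orientation matches the AlphaFold DB PAE viewer: residue 1 at the top-left
corner, scored residue along the x-axis, colour scale from 0 to the
declared maximum PAE.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .pae_io import PaeMatrix
from .segmentation import Segmentation


def _boundaries(seg: Segmentation) -> list[float]:
    """Internal domain boundaries as 0-based matrix positions (k-1 lines)."""
    ends = sorted(d.segments[-1].end for d in seg.domains)
    return [e - 0.5 for e in ends[:-1]]


def plot_pae(pae: PaeMatrix, seg: Segmentation | None = None,
             out: str | Path | None = None, ax=None):
    """Draw the PAE heatmap; overlay domain boundaries when given.

    Returns the matplotlib Axes; writes an image when ``out`` is given.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    vmax = pae.max_pae if pae.max_pae is not None else float(pae.values.max())
    im = ax.imshow(pae.values, origin="upper", cmap="Greens_r",
                   vmin=0.0, vmax=vmax, interpolation="nearest")
    ax.set_xlabel("Scored residue")
    ax.set_ylabel("Aligned residue")
    plt.colorbar(im, ax=ax, label="Expected position error (Å)")
    if seg is not None:
        for b in _boundaries(seg):
            ax.axhline(b, color="red", lw=0.8)
            ax.axvline(b, color="red", lw=0.8)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
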