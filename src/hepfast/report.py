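"""Percentile colour-coding and heat-map rendering of sensitivity matrices.

The convention follows the source figures: cells are classed by their
percentile within the whole matrix, green below the median and warm
colours above it, grading to red at the top.  Percentile breaks are
50/75/90/97.5 -> yellow/orange/red/darkred (the finer breaks above the
median are a rendering choice; only the green/median/red scheme is fixed
by the convention).  A column whose every entry exceeds the matrix median
is flagged — the "sensitive for all parameters" call-out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["COLOR_CLASSES", "PERCENTILE_BREAKS", "ColorCoded",
           "percentile_colorcode", "render_heatmap"]

COLOR_CLASSES = ("green", "yellow", "orange", "red", "darkred")
PERCENTILE_BREAKS = (50.0, 75.0, 90.0, 97.5)

#: Classes counted as "red" for call-out purposes.
RED_CLASSES = ("red", "darkred")


@dataclass
class ColorCoded:
    classes: pd.DataFrame                 # same shape, values from
                                          # COLOR_CLASSES
    above_median_columns: tuple[str, ...]  # every entry > matrix median
    breaks: tuple[float, ...]             # percentile cut values


def percentile_colorcode(matrix: pd.DataFrame) -> ColorCoded:
    """Class each cell by its percentile within the whole matrix.

    Ties sit below their break (a matrix of identical values is entirely
    green).  Requires finite entries in [0, 1].
    """
    if matrix.size == 0:
        raise ValueError("empty sensitivity matrix")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite sensitivity values")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("sensitivity indices must lie in [0, 1]")

    flat = np.sort(values.ravel())
    # strict percentile rank: fraction of all cells strictly below a value
    ranks = np.searchsorted(flat, values, side="left") / flat.size * 100.0
    idx = np.zeros(values.shape, dtype=int)
    for brk in PERCENTILE_BREAKS:
        idx += (ranks >= brk).astype(int)
    classes = pd.DataFrame(
        np.array(COLOR_CLASSES, dtype=object)[idx],
        index=matrix.index, columns=matrix.columns)

    median = float(np.median(values))
    flagged = tuple(col for col in matrix.columns
                    if (matrix[col].to_numpy() > median).all())
    return ColorCoded(classes, flagged, PERCENTILE_BREAKS)


def render_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    """Write a green-to-red percentile heat map (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    coded = percentile_colorcode(matrix)
    lookup = {name: i for i, name in enumerate(COLOR_CLASSES)}
    img = coded.classes.map(lookup.get).to_numpy(dtype=float)

    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.28 * matrix.shape[1]),
                 max(6.0, 0.14 * matrix.shape[0])))
    cmap = ListedColormap(["#2ca02c", "#ffdf00", "#ff8c00", "#e31a1c",
                           "#67000d"])
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0,
              vmax=len(COLOR_CLASSES) - 1, interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=5)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
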