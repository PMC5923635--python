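"""Minimal map rendering for lattice-based runs.

Real studies join the summary tables to polygon boundaries with GIS
tooling (see :func:`scsmap.summaries.merge_geojson_properties`); this
helper only renders a per-area surface on the regular grid used by the
synthetic scenarios, as a quick visual check.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_grid_surface"]


def plot_grid_surface(values, rows: int, cols: int, ax=None, title: str | None = None):
    """Choropleth-style image of a per-area quantity on a rows x cols grid.

    ``values`` follow the row-major area order of
    :func:`scsmap.areal_graph.grid_graph`.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    if values.size != rows * cols:
        raise ValueError(f"{values.size} values cannot fill a {rows}x{cols} grid")
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(values.reshape(rows, cols), cmap="viridis")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    return ax
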