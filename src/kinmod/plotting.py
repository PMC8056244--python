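"""Thin plotting helpers over matplotlib.

These functions only prepare axes and pass every keyword argument straight
through to matplotlib, so all styling remains in the caller's hands; they
return the Axes for further modification.  Data preparation (column
selection, heat-map ranges) lives in the analysis modules, keeping plotting
strictly optional.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .mca import mca_heatmap_data
from .simulate import TimeCourse


def plot_time_course(tc: TimeCourse, names: Sequence[str] | None = None,
                     ax=None, **kwargs):
    """Line plot of selected compounds (all by default) versus time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = tc.get_variables(list(names) if names else tc.compounds)
    for column in frame.columns[1:]:
        ax.plot(frame["time"], frame[column], label=column, **kwargs)
    ax.set_xlabel("time")
    ax.set_ylabel("concentration")
    ax.legend()
    return ax


def plot_phase_plane(X, Y, U, V, ax=None, trajectory=None, **kwargs):
    """Quiver plot of a phase-plane vector field, optional overlaid orbit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.quiver(X, Y, U, V, **kwargs)
    if trajectory is not None:
        ax.plot(trajectory[0], trajectory[1], color="crimson")
    return ax


def plot_heatmap(matrix, ax=None, **kwargs):
    """Heat map of a sensitivity matrix, colour range symmetric about zero.

    NaN cells (undefined scaled sensitivities) are hatched out.
    """
    import matplotlib.pyplot as plt

    data = mca_heatmap_data(matrix)
    if ax is None:
        _, ax = plt.subplots()
    values = np.ma.masked_invalid(data["values"])
    kwargs.setdefault("cmap", "RdBu_r")
    mesh = ax.pcolormesh(
        values, vmin=data["vmin"], vmax=data["vmax"], **kwargs
    )
    ax.set_xticks(np.arange(len(data["col_labels"])) + 0.5,
                  data["col_labels"], rotation=90)
    ax.set_yticks(np.arange(len(data["row_labels"])) + 0.5,
                  data["row_labels"])
    ax.figure.colorbar(mesh, ax=ax)
    return ax
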