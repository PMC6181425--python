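"""Static plot helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

from .tissue import Tissue, MODE_BULK, MODE_CRAWL, MODE_PS

MODE_COLORS = {MODE_BULK: "#cccccc", MODE_CRAWL: "#d62728", MODE_PS: "#2ca02c"}


def plot_tissue(tissue: Tissue, ax=None, color_by_mode: bool = True, **kw):
    """Draw the cell polygons, coloured by motility mode."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection
    if ax is None:
        _, ax = plt.subplots()
    polys = [tissue.x[c] for c in tissue.cells]
    colors = ([MODE_COLORS[int(m)] for m in tissue.mode]
              if color_by_mode else "#cccccc")
    ax.add_collection(PolyCollection(polys, facecolors=colors,
                                     edgecolors="k", linewidths=0.5, **kw))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax


def plot_traction(tf, ax=None, stride: int = 2, **kw):
    """Quiver plot of a reconstructed traction field."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    s = slice(None, None, stride)
    ax.quiver(tf.X[s, s], tf.Y[s, s], tf.T[s, s, 0], tf.T[s, s, 1], **kw)
    ax.set_aspect("equal")
    return ax


def plot_wound_area(traj, ax=None, **kw):
    """Log-linear wound area vs time."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    t = np.asarray(traj.area_times) / 60.0
    a = np.asarray(traj.areas)
    ax.semilogy(t[a > 0], a[a > 0], **kw)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("wound area (um$^2$)")
    return ax
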