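"""Display helpers: density contour maps and the paired-change waterfall."""

from __future__ import annotations

import numpy as np

from .spatial import DensityField


def plot_density_contours(field: DensityField, ax=None, levels: int = 8):
    """Contour map of a class density field over tile coordinates."""
    import matplotlib.pyplot as plt

    if field.empty:
        raise ValueError("cannot plot an empty density field")
    if ax is None:
        _, ax = plt.subplots()
    ny, nx = field.values.shape
    xs = field.origin_px[0] + np.arange(nx) * field.spacing_px
    ys = field.origin_px[1] + np.arange(ny) * field.spacing_px
    cs = ax.contourf(xs, ys, field.values, levels=levels, cmap="viridis")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.figure.colorbar(cs, ax=ax, label="density (cells/mm$^2$)")
    return ax


def plot_waterfall(change_table, ax=None, group_col: str = "taxane_second"):
    """Per-patient bars of the change in log10 median lymphocyte density,
    in the table's waterfall order (treatment sequence, then change)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    delta = change_table["delta_log_density"].to_numpy()
    colors = None
    if group_col in change_table:
        colors = np.where(change_table[group_col].to_numpy() > 0, "#d95f02", "#1b9e77")
    ax.bar(np.arange(len(delta)), delta, width=1.0, color=colors)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("patients (waterfall order)")
    ax.set_ylabel(r"$\Delta\log_{10}$ density")
    return ax
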