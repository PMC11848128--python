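"""Minimal density-profile plots (x versus P / F1 / F2)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_density_profile"]

_COLORS = {"P": "tab:blue", "F1": "tab:orange", "F2": "tab:green"}


def plot_density_profile(field, ax=None, epsilon: float | None = None):
    """Plot the three species' densities across space for one field.

    If ``epsilon`` is given, horizontal bars above the curves mark each
    species' occupied range. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    x = field.landscape.coordinates
    ymax = 0.0
    for name in ("P", "F1", "F2"):
        d = field.density(name)
        ax.plot(x, d, color=_COLORS[name], label=name)
        ymax = max(ymax, float(d.max(initial=0.0)))
    if epsilon is not None and ymax > 0:
        for k, name in enumerate(("P", "F1", "F2")):
            occ = np.flatnonzero(field.density(name) >= epsilon)
            if occ.size:
                y = ymax * (1.05 + 0.05 * k)
                ax.hlines(y, x[occ[0]], x[occ[-1]], color=_COLORS[name], lw=2)
    ax.set_xlabel("space x")
    ax.set_ylabel("density")
    ax.set_title(f"iteration {field.iteration}")
    ax.legend(frameon=False)
    return ax
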