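"""Quick-look plots of closure series and window fits."""

from __future__ import annotations

import numpy as np

from .kinetics import ClosureSeries, VelocityEstimate


def plot_closure(series: ClosureSeries,
                 estimate: VelocityEstimate | None = None,
                 ax=None):
    """Plot edge displacement vs time; overlay the fitted window line.

    Returns the matplotlib axes (imported lazily so headless batch use
    never touches a display backend).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = series.t_hours
    ax.plot(t, series.edge_displacement_um(smoothed=False), ".", ms=2,
            color="0.6", label="raw")
    ax.plot(t, series.edge_displacement_um(), "-", color="C0",
            label=f"smoothed (N={series.N})")
    if estimate is not None:
        a, b = estimate.window
        sel = (t >= a) & (t <= b)
        y = series.edge_displacement_um()[sel]
        x = t[sel]
        coeff = np.polyfit(x, y, 1)
        ax.plot(x, np.polyval(coeff, x), "--", color="C3",
                label=(f"fit {a:g}-{b:g} h: "
                       f"{estimate.v_um_per_h:.1f} um/h, "
                       f"$r^2$={estimate.r2:.3f}"))
    ax.set_xlabel("time after scratch (h)")
    ax.set_ylabel("edge displacement (um)")
    ax.set_title(series.position_id)
    ax.legend(fontsize=8)
    return ax
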