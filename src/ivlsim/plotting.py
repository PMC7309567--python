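"""Optional figure rendering: currentscape stacks and correlogram grids.

These helpers are conveniences over the analysis containers; nothing in the
pipeline depends on them.  They use the non-interactive matplotlib API and
return the created Figure.
"""

from __future__ import annotations

import numpy as np

from .analysis import Correlogram, CurrentDecomposition
from .simulator import TraceSet

__all__ = ["currentscape_figure", "correlogram_grid"]

# stable colour per channel across figures
_COLORS = {
    "H": "#17becf", "NaT": "#e377c2", "Kdrf": "#ff7f0e", "Kdrs": "#bcbd22",
    "KA": "#2ca02c", "M": "#9467bd", "CaT": "#8c564b", "CaL": "#d62728",
    "KCa": "#7f7f7f", "leak": "#a0522d", "syn_exc": "#1f77b4",
    "syn_inh": "#000080",
}


def _color(name: str):
    return _COLORS.get(name, "#333333")


def currentscape_figure(traces: TraceSet, dec: CurrentDecomposition,
                        site: str, window: tuple[float, float] | None = None):
    """Voltage trace over stacked percent contributions per pool.

    Top: membrane potential; middle: outward-current percent stack; bottom:
    inward-current percent stack (drawn downward), mirroring the standard
    currentscape layout.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = dec.time
    mask = np.ones(t.size, dtype=bool)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
    t = t[mask]
    v = traces.voltage[traces.site_index(site)][np.isin(traces.time,
                                                        dec.time)][mask]

    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 6),
                             gridspec_kw={"height_ratios": [1, 2, 2]})
    axes[0].plot(t, v, color="k", lw=0.6)
    axes[0].set_ylabel("V (mV)")

    for ax, frac, label, sign in (
            (axes[1], dec.outward_fraction[:, mask], "outward %", 1.0),
            (axes[2], dec.inward_fraction[:, mask], "inward %", 1.0)):
        filled = np.nan_to_num(frac, nan=0.0)
        base = np.zeros(t.size)
        for j, name in enumerate(dec.names):
            top = base + sign * filled[j]
            ax.fill_between(t, base, top, color=_color(name), label=name,
                            linewidth=0)
            base = top
        ax.set_ylim(0, 1)
        ax.set_ylabel(label)
    axes[1].legend(ncol=4, fontsize=7, loc="upper right")
    axes[2].set_xlabel("time (ms)")
    fig.align_ylabels(axes)
    return fig


def correlogram_grid(correlograms: dict[str, Correlogram], ncols: int = 4):
    """Small-multiple grid of correlograms keyed by a label (e.g. 'NaT*V')."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = list(correlograms)
    nrows = int(np.ceil(len(names) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                             sharex=True, sharey=True, squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for k, name in enumerate(names):
        ax = axes[k // ncols][k % ncols]
        ax.axis("on")
        cg = correlograms[name]
        ax.plot(cg.lags, cg.values, lw=0.9)
        ax.axhline(0.0, color="gray", lw=0.5, ls="--")
        ax.axvline(0.0, color="gray", lw=0.5, ls="--")
        ax.set_ylim(-1.05, 1.05)
        ax.set_title(name, fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("lag (ms)")
    return fig
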