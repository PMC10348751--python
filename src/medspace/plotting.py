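"""Basic trend plots for sweep tables."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_sweep"]

_MODE_STYLE = {"spatial": dict(marker="s", fillstyle="none"),
               "well_mixed": dict(marker="o"),
               "infinite_dispersal": dict(marker="^", fillstyle="none")}


def plot_sweep(aggregates, x: str, out_path, logx: bool = False,
               y: str = "mean_richness"):
    """Plot mean richness (+/- bootstrap CI) against one swept parameter,
    one line per mode; writes an image file."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for mode, sub in aggregates.groupby("mode"):
        sub = sub.sort_values(x)
        yerr = (sub[y] - sub["ci_lower"], sub["ci_upper"] - sub[y])
        ax.errorbar(sub[x], sub[y], yerr=yerr, capsize=3,
                    label=mode.replace("_", " "),
                    **_MODE_STYLE.get(mode, {}))
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel("mean richness")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
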