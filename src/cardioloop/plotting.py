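"""PV-loop and strain-bar figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_pv_loops", "plot_strain_bars"]


def plot_pv_loops(traces: dict, path=None):
    """Overlayed LV pressure-volume loops, one per labelled trace."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for label, tr in traces.items():
        ax.plot(tr.v_lv, tr.p_lv, label=label, lw=1.5)
    ax.set_xlabel("LV volume (mL)")
    ax.set_ylabel("LV pressure (mmHg)")
    ax.legend(frameon=False)
    ax.set_title("Pressure-volume loops")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_strain_bars(reports: dict, path=None):
    """Family-average strains (left) and regional longitudinal strains
    (right) as grouped bars, one group color per labelled report."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    fams = ["radial", "circumferential", "longitudinal"]
    n = len(reports)
    width = 0.8 / n
    for i, (label, rep) in enumerate(reports.items()):
        means = [getattr(rep, f)[0] for f in fams]
        sds = [getattr(rep, f)[1] for f in fams]
        xs = [j + (i - (n - 1) / 2) * width for j in range(len(fams))]
        ax1.bar(xs, means, width=width, yerr=sds, capsize=3, label=label)
        regions = list(rep.regional_longitudinal)
        vals = [rep.regional_longitudinal[r] for r in regions]
        xs = [j + (i - (n - 1) / 2) * width for j in range(len(regions))]
        ax2.bar(xs, vals, width=width, label=label)
    ax1.set_xticks(range(len(fams)), fams)
    ax1.set_ylabel("engineering strain")
    ax1.axhline(0, color="k", lw=0.5)
    ax1.set_title("Average strains")
    ax2.set_xticks(range(4), regions)
    ax2.axhline(0, color="k", lw=0.5)
    ax2.set_title("Regional longitudinal strain")
    ax1.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
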