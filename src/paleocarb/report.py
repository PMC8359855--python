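"""Figure and table generation for forward runs and posterior summaries.

Every figure's numeric content is also emitted as CSV next to the image, so
plots are a view of the run products rather than a second source of truth.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .inversion import PosteriorChain, PosteriorSummary
from .record import IsotopeRecord

logger = logging.getLogger(__name__)

#: envelope panels drawn by default: (column, axis label, log-y)
_PANELS = (
    ("delta_carb_buried", r"$\delta^{13}$C carb buried (permil)", False),
    ("delta_org_buried", r"$\delta^{13}$C org buried (permil)", False),
    ("f_org", r"$f_{org}$ (true)", False),
    ("f_org_apparent", r"$f_{org}(-5.5)$ (apparent)", False),
    ("delta_inputs", r"$\delta^{13}$C inputs (permil)", False),
    ("K_oxy", r"$K_{oxy}$", True),
    ("F_burial_org", "organic burial (mol C/yr)", True),
    ("F_outg", "total outgassing (mol C/yr)", True),
    ("R_org", r"$R_{org}$ (mol C)", True),
    ("R_carb", r"$R_{carb}$ (mol C)", True),
    ("pCO2_ppm", r"pCO$_2$ (ppm)", True),
    ("T_s", r"$T_s$ (K)", False),
)


def _band(ax, df, color="C0"):
    ax.fill_between(df["t_ga"], df["q025"], df["q975"], alpha=0.25,
                    color=color, lw=0)
    ax.fill_between(df["t_ga"], df["q16"], df["q84"], alpha=0.35,
                    color=color, lw=0)
    ax.plot(df["t_ga"], df["q50"], color=color, lw=1.5)


def plot_envelopes(summary: PosteriorSummary, out_dir,
                   record: IsotopeRecord | None = None) -> Path:
    """Time-envelope panel figure (median and 68/95% credible bands)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panels = [p for p in _PANELS if p[0] in summary.envelopes]
    if not panels:
        logger.warning("no envelopes in summary; nothing to plot")
        return out_dir
    ncol = 3
    nrow = int(np.ceil(len(panels) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.2 * ncol, 3.0 * nrow),
                             squeeze=False)
    for ax, (col, label, logy) in zip(axes.ravel(), panels):
        df = summary.envelopes[col]
        _band(ax, df)
        if record is not None and col == "delta_carb_buried":
            ax.errorbar(record.age_ga, record.carb_mean, yerr=record.carb_sd,
                        fmt="o", ms=3, color="k", lw=0.8)
        if record is not None and col == "delta_org_buried":
            ax.errorbar(record.age_ga, record.org_mean, yerr=record.org_sd,
                        fmt="o", ms=3, color="k", lw=0.8)
        if col == "K_oxy":
            ax.axhline(1.0, color="r", ls="--", lw=0.8)
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("age (Ga)")
        ax.set_ylabel(label)
        ax.invert_xaxis()
    for ax in axes.ravel()[len(panels):]:
        ax.set_visible(False)
    fig.tight_layout()
    path = out_dir / f"envelopes_{summary.scenario_name}.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    summary.envelopes_to_csv(out_dir)
    return path


def plot_fold_change(chains: dict[str, PosteriorChain], out_dir,
                     bins: int = 40) -> Path:
    """Normalized fold-change posterior histograms, one per scenario."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5.5, 3.8))
    rows = []
    for i, (name, chain) in enumerate(chains.items()):
        fc = chain.flat_blobs()["fold_change"]
        fc = fc[np.isfinite(fc)]
        fc = fc[(fc > 0) & (fc < 25)]
        if len(fc) == 0:
            continue
        ax.hist(fc, bins=bins, density=True, histtype="step",
                color=f"C{i}", label=name)
        rows.append({"scenario": name, "median": float(np.median(fc)),
                     "q16": float(np.quantile(fc, 0.16)),
                     "q84": float(np.quantile(fc, 0.84)), "n": len(fc)})
    ax.set_xlabel("fold change in fractional organic burial")
    ax.set_ylabel("posterior density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / "fold_change.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(out_dir / "fold_change.csv", index=False)
    return path


def plot_corner(chain: PosteriorChain, out_dir,
                names: tuple = ("j1", "j2", "j3")) -> Path:
    """Small pairwise-marginal (corner-style) plot for selected parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idx = [chain.param_names.index(n) for n in names if n in chain.param_names]
    names = [chain.param_names[i] for i in idx]
    X = chain.flat()[:, idx]
    k = len(idx)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k))
    for i in range(k):
        for j in range(k):
            ax = axes[i, j]
            if j > i:
                ax.set_visible(False)
            elif i == j:
                ax.hist(X[:, i], bins=30, color="C0", histtype="stepfilled")
                ax.set_yticks([])
            else:
                ax.hist2d(X[:, j], X[:, i], bins=30, cmap="Blues")
            if i == k - 1:
                ax.set_xlabel(names[j])
            if j == 0 and i > 0:
                ax.set_ylabel(names[i])
    fig.tight_layout()
    path = out_dir / f"corner_{chain.scenario.name}.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
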