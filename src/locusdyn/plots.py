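"""Figure panels: MSD power laws, VACF collapse, position distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from locusdyn.dynamics import CollapseResult, MSDResult, PowerLawFit, fbm_vacf_theory

__all__ = ["plot_msd", "plot_vacf_collapse", "plot_position_distribution", "save"]


def plot_msd(
    results: dict[str, MSDResult],
    fits: dict[str, PowerLawFit] | None = None,
    ax=None,
):
    """Log-log MSD curves per component with their power-law fits."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    for name, res in results.items():
        if res.curves is not None:
            for row in res.curves:
                ax.loglog(res.lags_s, row, color="0.8", lw=0.4, zorder=1)
        ax.loglog(res.lags_s, res.msd, lw=2, label=name, zorder=3)
        if fits and name in fits:
            f = fits[name]
            tau = res.lags_s
            ax.loglog(
                tau,
                f.D * tau**f.alpha,
                "--",
                lw=1,
                zorder=4,
                label=rf"{name}: $\alpha$={f.alpha:.2f}$\pm${f.alpha_se:.2f}",
            )
    ax.set_xlabel(r"lag $\tau$ (s)")
    ax.set_ylabel(r"MSD (nm$^2$)")
    ax.legend(fontsize=7)
    return ax


def plot_vacf_collapse(collapse: CollapseResult, alpha: float | None = None, ax=None):
    """Normalized VACF curves on the rescaled lag xi = tau/delta."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    xi = collapse.table.index.to_numpy()
    for col in collapse.table.columns:
        if col.startswith("delta="):
            ax.plot(xi, collapse.table[col], "o-", ms=2.5, lw=0.8, label=col)
    if alpha is not None:
        fine = np.linspace(xi.min(), xi.max(), 200)
        ax.plot(fine, fbm_vacf_theory(fine, alpha), "k--", lw=1.5, label=rf"FBM, $\alpha$={alpha:.2f}")
    ax.axhline(0.0, color="0.6", lw=0.5)
    ax.set_xlabel(r"$\xi = \tau/\delta$")
    ax.set_ylabel(r"$C_u^\delta(\tau)\,/\,C_u^\delta(0)$")
    ax.legend(fontsize=7)
    return ax


def plot_position_distribution(tables: dict[str, pd.DataFrame], ax=None):
    """Normalized longitudinal position histograms (fraction of cell length)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    for name, tab in tables.items():
        width = tab["bin_left"].diff().dropna().median()
        density = tab["count"] / max(tab["count"].sum(), 1) / width
        ax.step(tab["bin_left"], density, where="post", label=name)
    ax.set_xlabel("longitudinal position / cell length")
    ax.set_ylabel("probability density")
    ax.legend(fontsize=8)
    return ax


def save(ax, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
    return path
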