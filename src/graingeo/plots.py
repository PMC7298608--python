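"""Diagnostic figures: selection wealth/p-value panels and cross-validation plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_ledger", "plot_crossval"]


def plot_ledger(ledger, path: str | Path) -> Path:
    """Two panels: alpha-wealth over the test sequence; p-values vs thresholds."""
    t = ledger.to_frame()
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    ax1.step(t["order"], t["wealth"], where="post", color="k")
    ax1.axhline(0, lw=0.5, color="grey")
    ax1.set_ylabel("alpha-wealth")
    ax2.semilogy(t["order"], t["p"].clip(lower=1e-12), "o", mfc="none", label="p-value")
    ax2.semilogy(t["order"], t["alpha"], "ks", label="threshold")
    ax2.set_xlabel("test order")
    ax2.set_ylabel("p / threshold")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_crossval(report, coords: np.ndarray, path: str | Path) -> Path:
    """Four panels: observed vs predicted, standardized-error histogram,
    SSPE map and PEV map."""
    t = report.table
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    ax = axes[0, 0]
    ax.plot(t["predicted"], t["observed"], "o", ms=3, alpha=0.6)
    lims = [min(t["predicted"].min(), t["observed"].min()),
            max(t["predicted"].max(), t["observed"].max())]
    ax.plot(lims, lims, "k-", lw=0.8)
    ax.set_xlabel("predicted (log)")
    ax.set_ylabel("observed (log)")
    ax = axes[0, 1]
    std_err = t["error"] / np.sqrt(t["pev"].clip(lower=1e-12))
    ax.hist(std_err, bins=25, color="grey")
    ax.set_xlabel("standardized error")
    for k, (col, title) in enumerate([("sspe", "SSPE"), ("pev", "PEV")]):
        ax = axes[1, k]
        sc = ax.scatter(coords[: len(t), 0], coords[: len(t), 1], c=t[col],
                        s=8, cmap="viridis")
        fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_title(title)
        ax.set_aspect("equal")
    fig.suptitle(f"{report.tag}: mean SSPE {report.mean_sspe:.2f}, "
                 f"median {report.median_sspe:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
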