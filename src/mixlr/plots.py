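"""Functional diagnostic plots (ratio traces, LR distributions)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .deconvolution import WeightedGenotypes


def plot_ratio_trace(wg: WeightedGenotypes, path: str | Path) -> None:
    """Per-chain mixture-proportion traces (post burn-in)."""
    chains, _, n = wg.phi_traces.shape
    fig, axes = plt.subplots(n, 1, sharex=True, figsize=(8, 1.8 * n), squeeze=False)
    for k in range(n):
        ax = axes[k, 0]
        for c in range(chains):
            ax.plot(wg.phi_traces[c, :, k], lw=0.5, alpha=0.7)
        ax.set_ylabel(f"$\\phi_{{{k + 1}}}$")
        ax.set_ylim(0, 1)
    axes[-1, 0].set_xlabel("post burn-in sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_insilico_lr_distribution(results: pd.DataFrame, path: str | Path) -> None:
    """Histogram of in silico non-contributor log10 LRs by population."""
    fig, ax = plt.subplots(figsize=(8, 4))
    for pop, sub in results.groupby("population"):
        ax.hist(sub["log10_overall"], bins=40, alpha=0.5, label=str(pop))
    ax.axvline(0.0, color="k", ls="--", lw=1)
    ax.set_xlabel("log10 LR")
    ax.set_ylabel("count")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_het_balance(het_balance: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(het_balance["expected_height"], het_balance["log_ratio"], s=6, alpha=0.4)
    ax.axhline(0.0, color="k", lw=1)
    ax.set_xlabel("expected peak height (RFU)")
    ax.set_ylabel("log heterozygote balance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
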