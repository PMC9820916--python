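"""Plain-styled figures: correlation heatmap, PCA variable circle, importance."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import CorrelationMatrix, PCAResult


def plot_correlation_matrix(corr: CorrelationMatrix, path) -> None:
    """Heatmap of Kendall τ; non-significant pairs are crossed out."""
    tau = corr.tau.to_numpy()
    k = tau.shape[0]
    fig, ax = plt.subplots(figsize=(0.35 * k + 2.5, 0.35 * k + 2))
    im = ax.imshow(tau, vmin=-1, vmax=1, cmap="RdBu")
    sig = corr.significant.to_numpy()
    for i in range(k):
        for j in range(k):
            if i != j and not sig[i, j]:
                ax.plot(j, i, "x", color="0.3", ms=5)
    ax.set_xticks(range(k), corr.variables, rotation=90, fontsize=7)
    ax.set_yticks(range(k), corr.variables, fontsize=7)
    fig.colorbar(im, ax=ax, label="Kendall tau")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_circle(res: PCAResult, path, dims=(0, 1)) -> None:
    """Variable map on the correlation circle for two dimensions."""
    i, j = dims
    fig, ax = plt.subplots(figsize=(6, 6))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="0.7", lw=1)
    for var in res.coords.index:
        x, y = res.coords.iloc[:, i][var], res.coords.iloc[:, j][var]
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="C0", lw=0.8))
        ax.text(x * 1.05, y * 1.05, var, fontsize=7, ha="center")
    ax.axhline(0, color="0.85", lw=0.8)
    ax.axvline(0, color="0.85", lw=0.8)
    ax.set_xlabel(f"Dim {i + 1} ({res.pct_variance[i]:.1f}%)")
    ax.set_ylabel(f"Dim {j + 1} ({res.pct_variance[j]:.1f}%)")
    ax.set_aspect("equal")
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importance(importance, path, title="") -> None:
    """Horizontal bar chart of normalized fitness-weighted importance."""
    imp = importance.sort_values()
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(imp) + 1.5))
    ax.barh(range(len(imp)), imp.to_numpy(), color="C0")
    ax.set_yticks(range(len(imp)), imp.index, fontsize=8)
    ax.set_xlabel("normalized fitness-weighted importance")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
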