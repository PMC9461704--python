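"""Optional matplotlib figures mirroring the benchmark's diagnostic plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def coverage_bars(counts: pd.DataFrame, path: Path) -> None:
    """Stacked above-LOD counts per protocol, one panel per tissue."""
    tissues = sorted(counts["tissue"].unique())
    fig, axes = plt.subplots(1, len(tissues), figsize=(4 * len(tissues), 4), squeeze=False)
    for ax, tissue in zip(axes[0], tissues):
        sub = counts[counts["tissue"] == tissue]
        pivot = sub.pivot_table(
            index="protocol", columns="class", values="count", aggfunc="sum", fill_value=0
        )
        pivot.plot.bar(stacked=True, ax=ax, legend=False, width=0.8)
        ax.set_title(tissue)
        ax.set_ylabel("metabolites above LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def cv_median_bars(cv_sum: pd.DataFrame, path: Path) -> None:
    """Median replicate CV per tissue x protocol with MAD error bars."""
    fig, ax = plt.subplots(figsize=(10, 4))
    labels = cv_sum["tissue"] + "/" + cv_sum["protocol"]
    ax.bar(labels, cv_sum["cv_median"], yerr=cv_sum["cv_mad"], capsize=2)
    ax.set_ylabel("median CV")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def score_scatter(pca_output, samples: pd.DataFrame, path: Path) -> None:
    """PC1 vs PC2 score plot coloured by tissue."""
    scores = pca_output.scores
    meta = samples.set_index("sample_id").loc[scores.index]
    fig, ax = plt.subplots(figsize=(5, 5))
    for tissue, grp in scores.groupby(meta["tissue"]):
        ax.scatter(grp.iloc[:, 0], grp.iloc[:, 1], label=tissue, s=15)
    evf = pca_output.explained_variance_fraction
    ax.set_xlabel(f"{scores.columns[0]} ({100 * evf.iloc[0]:.1f}%)")
    if scores.shape[1] > 1:
        ax.set_ylabel(f"{scores.columns[1]} ({100 * evf.iloc[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
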