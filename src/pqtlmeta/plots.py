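"""Basic diagnostic plots (matplotlib, optional dependency).

Deliberately minimal: a scree plot for choosing the number of genotype
PCs, a stacked variance-decomposition bar chart, and a p-value
concordance scatter for the cell-count sensitivity analysis.
"""

from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def scree_plot(eigenvalues, path):
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4, 3))
    k = len(eigenvalues)
    ax.bar(np.arange(1, k + 1), eigenvalues, color="0.4")
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def variance_barplot(decompositions, path):
    """Stacked bars: clinical / top SNP / second SNP / unexplained."""
    plt = _pyplot()
    labels = [f"{d.analyte_id} ({d.cohort})" for d in decompositions]
    parts = np.array([d.components for d in decompositions])
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(labels)), 3.5))
    bottom = np.zeros(len(labels))
    for j, (name, color) in enumerate(
        [("clinical", "seagreen"), ("top SNP", "firebrick"),
         ("2nd SNP", "sandybrown"), ("unexplained", "0.8")]
    ):
        ax.bar(labels, parts[:, j], bottom=bottom, label=name, color=color)
        bottom += parts[:, j]
    ax.set_ylabel("fraction of variance")
    ax.legend(fontsize=7)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def concordance_scatter(sensitivity, path):
    """-log10 p with vs without cell-count covariates, one dot per pair."""
    plt = _pyplot()
    t = sensitivity.table
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(-np.log10(t["p_base"]), -np.log10(t["p_cbc"]), s=4, alpha=0.4)
    lim = max(ax.get_xlim()[1], ax.get_ylim()[1])
    ax.plot([0, lim], [0, lim], lw=0.8, color="0.5")
    ax.set_xlabel("-log10 p (base)")
    ax.set_ylabel("-log10 p (+ cell counts)")
    ax.set_title(f"r = {sensitivity.corr_all:.4f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
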