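"""Minimal diagnostic plots: a DE volcano and an enrichment bar chart."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def volcano(de_table: pd.DataFrame, path: str | Path, fdr_cut: float = 0.001) -> Path:
    """log2FC vs -log10 adjusted p, DE genes highlighted."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    x = de_table["log2fc"]
    y = -np.log10(np.clip(de_table["adj_p"], 1e-300, None))
    de = de_table.get("status", pd.Series("not_de", index=de_table.index)) != "not_de"
    ax.scatter(x[~de], y[~de], s=4, c="0.7", label="not DE")
    ax.scatter(x[de], y[de], s=6, c="crimson", label="DE")
    ax.axhline(-np.log10(fdr_cut), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (case - control)")
    ax.set_ylabel("-log10 adjusted p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def enrichment_bars(rows: pd.DataFrame, path: str | Path, top: int = 5) -> Path:
    """Horizontal bars of -log10 p for the top enriched sets."""
    path = Path(path)
    head = rows.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.6 * max(len(head), 1) + 1))
    ax.barh(head["set_name"], -np.log10(np.clip(head["p_value"], 1e-300, None)), color="steelblue")
    ax.set_xlabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
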