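"""Bubble-chart visualization of enrichment results across runs.

Gene sets sit on the y axis, runs (lncRNA x metric) on the x axis; point
size scales with -log10(q_fdr), color with NES. Every figure gets a
sidecar TSV holding exactly the plotted numbers — the plot is never the
only record.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .gsea import EnrichmentResult

PLOT_FORMATS = ("png", "pdf", "svg")


def _plot_frame(
    results: dict[str, EnrichmentResult], top_k: int, q_threshold: float
) -> pd.DataFrame:
    """Tidy table of (pathway, run, nes, q_fdr, size) for plottable sets.

    Sets are kept if q_fdr < q_threshold in at least one run, ordered by
    mean NES descending (ties by name), truncated to top_k.
    """
    frames = []
    for label, res in results.items():
        t = res.table.reset_index()[["pathway", "size", "nes", "q_fdr"]].copy()
        t["run"] = label
        frames.append(t)
    tidy = pd.concat(frames, ignore_index=True)
    passing = tidy.loc[tidy["q_fdr"] < q_threshold, "pathway"].unique()
    tidy = tidy[tidy["pathway"].isin(passing)]
    if tidy.empty:
        return tidy
    order = (
        tidy.groupby("pathway")["nes"]
        .mean()
        .reset_index()
        .sort_values(by=["nes", "pathway"], ascending=[False, True], kind="stable")
    )
    keep = order["pathway"].head(top_k).tolist()
    tidy = tidy[tidy["pathway"].isin(keep)].copy()
    tidy["pathway"] = pd.Categorical(tidy["pathway"], categories=keep, ordered=True)
    return tidy.sort_values(["pathway", "run"], kind="stable").reset_index(drop=True)


def plot_enrichment(
    results: dict[str, EnrichmentResult],
    path: str | Path,
    top_k: int = 20,
    q_threshold: float = 0.05,
    fmt: str = "png",
) -> pd.DataFrame:
    """Write the bubble chart and its sidecar TSV; return the plotted table.

    If no gene set passes the q threshold in any run, an annotated empty
    plot is still written (plus an empty sidecar) so batch pipelines have
    a record.
    """
    if fmt not in PLOT_FORMATS:
        raise ConfigError(f"plot format must be one of {PLOT_FORMATS}, got {fmt!r}")
    if not results:
        raise ValidationError("no enrichment results to plot")
    if top_k < 1:
        raise ConfigError("top_k must be >= 1")
    path = Path(path).with_suffix(f".{fmt}")
    sidecar = path.with_suffix(".tsv")
    tidy = _plot_frame(results, top_k, q_threshold)
    tidy.to_csv(sidecar, sep="\t", index=False)

    fig, ax = plt.subplots(
        figsize=(2.0 + 1.2 * len(results), 1.5 + 0.3 * max(1, tidy["pathway"].nunique() if not tidy.empty else 1))
    )
    if tidy.empty:
        ax.text(
            0.5, 0.5, f"no gene set with q < {q_threshold}",
            ha="center", va="center", transform=ax.transAxes,
        )
        ax.set_xticks([])
        ax.set_yticks([])
    else:
        runs = sorted(tidy["run"].unique())
        pathways = list(tidy["pathway"].cat.categories)
        x = tidy["run"].map({r: i for i, r in enumerate(runs)})
        y = tidy["pathway"].map({p: i for i, p in enumerate(pathways)})
        # size floor mirrors the Monte-Carlo p floor: q can't be 0
        logq = -np.log10(np.clip(tidy["q_fdr"], 1e-10, 1.0))
        sc = ax.scatter(
            x, y, s=30 + 60 * logq, c=tidy["nes"], cmap="RdBu_r",
            vmin=-max(abs(tidy["nes"])), vmax=max(abs(tidy["nes"])),
            edgecolors="grey", linewidths=0.5,
        )
        ax.set_xticks(range(len(runs)), runs, rotation=45, ha="right")
        ax.set_yticks(range(len(pathways)), pathways, fontsize=8)
        ax.invert_yaxis()
        fig.colorbar(sc, ax=ax, label="NES", shrink=0.6)
    ax.set_title("lncRNA-associated gene sets")
    fig.tight_layout()
    # strip embedded timestamps so identical inputs give identical bytes
    metadata = {"svg": {"Date": None}, "pdf": {"CreationDate": None}, "png": None}[fmt]
    fig.savefig(path, format=fmt, metadata=metadata)
    plt.close(fig)
    return tidy
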