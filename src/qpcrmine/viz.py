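"""The plot family: ten numbered treatment-comparison and QC views.

Every plot kind is addressed by an integer 1–10 and renders two artifacts
atomically (both appear or neither): the image itself and a sidecar CSV of
exactly the plotted values, so tests and users can check content without
pixel comparison.

====  =========================================================
kind  view
====  =========================================================
1     bars ± SE of one gene's fold change across treatments
2     grouped bars of all genes by treatment
3     dot-and-error comparison of treatments per gene
4     box plots of per-replicate folds per treatment
5     line profiles across the second factor, one line per
      first-factor level
6     radar chart of expression by treatment (one polygon/gene)
7     correlation matrix plot (Pearson r, significance-aware)
8     clustered heatmap (Ward/Euclidean ordering, z-scored)
9     PCA biplot on the feature correlation matrix
10    QC view of raw Ct distributions per gene
====  =========================================================
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ctio import CtWell, TraitTable
from .errors import ConfigError, DesignError
from .relquant import ExpressionEstimate
from .multivar import pca_correlation, pearson_matrix, standardize, ward_cluster

#: Fixed palette so renders are deterministic across runs.
PALETTE = (
    "#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3",
    "#937860", "#da8bc3", "#8c8c8c", "#ccb974", "#64b5cd",
)

N_KINDS = 10


@dataclass
class PlotRequest:
    """What to draw: a kind number plus whichever data the kind needs.

    ``estimates`` feeds kinds 1–6 (kind 2/6 also accept a ``table`` of
    means with SEs); ``folds`` (per-replicate Series) feeds kind 4;
    ``table`` feeds kinds 7–9; ``wells`` feeds kind 10.
    """

    kind: int
    out_path: str | Path = "plot.png"
    estimates: Sequence[ExpressionEstimate] | None = None
    table: TraitTable | None = None
    folds: pd.Series | None = None
    wells: Iterable[CtWell] | None = None
    title: str = ""
    gene: str | None = None
    options: dict = field(default_factory=dict)


def render_plot(request: PlotRequest) -> tuple[Path, Path]:
    """Render one plot; returns (image path, sidecar path).

    The sidecar at ``<out_path>.data.csv`` holds the plotted values
    verbatim.  Both files are written to temporaries and renamed into
    place together, so a failed render leaves nothing behind.
    """
    if not isinstance(request.kind, int) or not 1 <= request.kind <= N_KINDS:
        raise ConfigError(f"plot kind must be an integer in [1, {N_KINDS}], got {request.kind!r}")
    out_path = Path(request.out_path)
    sidecar_path = Path(str(out_path) + ".data.csv")
    renderer = _RENDERERS[request.kind]

    fig, sidecar = renderer(request)
    if request.title:
        fig.suptitle(request.title)
    out_dir = out_path.parent if str(out_path.parent) else Path(".")
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = out_path.suffix or ".png"
    tmp_img = tempfile.NamedTemporaryFile(dir=out_dir, suffix=suffix, delete=False)
    tmp_csv = tempfile.NamedTemporaryFile(dir=out_dir, suffix=".csv", delete=False)
    try:
        fig.savefig(tmp_img.name, format=suffix.lstrip("."))
        sidecar.to_csv(tmp_csv.name, index=False)
        os.replace(tmp_img.name, out_path)
        os.replace(tmp_csv.name, sidecar_path)
    except Exception:
        for tmp in (tmp_img.name, tmp_csv.name):
            if os.path.exists(tmp):
                os.unlink(tmp)
        raise
    finally:
        plt.close(fig)
    return out_path, sidecar_path


def _require(value, what: str):
    if value is None:
        raise DesignError(f"this plot kind requires {what}")
    return value


def _mean_se_frames(request: PlotRequest) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment × gene mean and SE frames from estimates or a trait table."""
    if request.estimates is not None:
        rows = {}
        ses = {}
        for e in request.estimates:
            rows.setdefault(e.treatment, {})[e.target_gene] = e.fold_mean
            ses.setdefault(e.treatment, {})[e.target_gene] = e.fold_se
        idx = pd.MultiIndex.from_tuples(rows.keys())
        means = pd.DataFrame([rows[t] for t in rows], index=idx)
        se = pd.DataFrame([ses[t] for t in ses], index=idx)
        return means, se
    table = _require(request.table, "expression estimates or a trait table of means")
    se = table.se if table.se is not None else table.values * np.nan
    return table.values, se


def _treatment_labels(index: pd.Index) -> list[str]:
    return ["_".join(map(str, t)) if isinstance(t, tuple) else str(t) for t in index]


def _sidecar_long(means: pd.DataFrame, se: pd.DataFrame) -> pd.DataFrame:
    out = means.stack().rename("mean").to_frame()
    out["se"] = se.stack()
    out = out.reset_index()
    out.columns = [*[f"factor{i+1}" for i in range(means.index.nlevels)], "gene", "mean", "se"]
    return out


def _pick_gene(request: PlotRequest, means: pd.DataFrame) -> str:
    gene = request.gene or means.columns[0]
    if gene not in means.columns:
        raise DesignError(f"gene {gene!r} not present in the data")
    return gene


def _plot_bars(request: PlotRequest):
    means, se = _mean_se_frames(request)
    gene = _pick_gene(request, means)
    labels = _treatment_labels(means.index)
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(labels)), 4))
    ax.bar(labels, means[gene], yerr=se[gene].fillna(0), color=PALETTE[0], capsize=3)
    ax.set_ylabel("relative expression (fold)")
    ax.set_xlabel("treatment")
    ax.set_title(gene)
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    return fig, _sidecar_long(means[[gene]], se[[gene]])


def _plot_grouped_bars(request: PlotRequest):
    means, se = _mean_se_frames(request)
    labels = _treatment_labels(means.index)
    x = np.arange(len(labels))
    width = 0.8 / len(means.columns)
    fig, ax = plt.subplots(figsize=(max(7, 0.6 * len(labels)), 4.5))
    for i, gene in enumerate(means.columns):
        ax.bar(
            x + i * width,
            means[gene],
            width,
            yerr=se[gene].fillna(0),
            label=str(gene),
            color=PALETTE[i % len(PALETTE)],
            capsize=2,
        )
    ax.set_xticks(x + 0.4 - width / 2, labels, rotation=90)
    ax.set_ylabel("relative expression (fold)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig, _sidecar_long(means, se)


def _plot_dots(request: PlotRequest):
    means, se = _mean_se_frames(request)
    labels = _treatment_labels(means.index)
    fig, ax = plt.subplots(figsize=(max(7, 0.6 * len(labels)), 4.5))
    x = np.arange(len(labels))
    for i, gene in enumerate(means.columns):
        ax.errorbar(
            x, means[gene], yerr=se[gene].fillna(0), fmt="o",
            label=str(gene), color=PALETTE[i % len(PALETTE)], capsize=3,
        )
    ax.set_xticks(x, labels, rotation=90)
    ax.set_ylabel("relative expression (fold)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig, _sidecar_long(means, se)


def _plot_box(request: PlotRequest):
    folds = _require(request.folds, "per-replicate folds (a fold-profile Series)")
    frame = folds.rename("fold").reset_index()
    frame["label"] = [
        "_".join(map(str, t)) + ":" + str(g) for t, g in zip(frame["treatment"], frame["target"])
    ]
    groups = [g["fold"].to_numpy() for _, g in frame.groupby("label", sort=False)]
    labels = list(dict.fromkeys(frame["label"]))
    fig, ax = plt.subplots(figsize=(max(7, 0.35 * len(labels)), 4.5))
    ax.boxplot(groups, tick_labels=labels)
    ax.tick_params(axis="x", rotation=90)
    ax.set_ylabel("replicate fold change")
    fig.tight_layout()
    return fig, frame[["treatment", "replicate", "target", "fold"]]


def _plot_lines(request: PlotRequest):
    means, se = _mean_se_frames(request)
    gene = _pick_gene(request, means)
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    if means.index.nlevels >= 2:
        wide = means[gene].unstack(level=0)
        for i, col in enumerate(wide.columns):
            ax.plot(wide.index.astype(str), wide[col], "o-",
                    label=f"{means.index.names[0] or 'A'}={col}",
                    color=PALETTE[i % len(PALETTE)])
        ax.set_xlabel(means.index.names[-1] or "factor level")
        ax.legend(fontsize=8)
    else:
        ax.plot(_treatment_labels(means.index), means[gene], "o-", color=PALETTE[0])
        ax.set_xlabel("treatment")
    ax.set_ylabel("relative expression (fold)")
    ax.set_title(gene)
    fig.tight_layout()
    return fig, _sidecar_long(means[[gene]], se[[gene]])


def _plot_radar(request: PlotRequest):
    means, se = _mean_se_frames(request)
    labels = _treatment_labels(means.index)
    k = len(labels)
    angles = np.linspace(0, 2 * np.pi, k, endpoint=False)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"projection": "polar"})
    for i, gene in enumerate(means.columns):
        vals = means[gene].to_numpy(float)
        closed = np.append(vals, vals[:1])
        ang = np.append(angles, angles[:1])
        ax.plot(ang, closed, label=str(gene), color=PALETTE[i % len(PALETTE)])
        ax.fill(ang, closed, alpha=0.08, color=PALETTE[i % len(PALETTE)])
    ax.set_xticks(angles, labels, fontsize=7)
    ax.legend(fontsize=8, loc="upper right", bbox_to_anchor=(1.25, 1.05))
    fig.tight_layout()
    return fig, _sidecar_long(means, se)


def _plot_corr(request: PlotRequest):
    table = _require(request.table, "a trait table")
    cm = pearson_matrix(table, alpha=request.options.get("alpha", 0.05))
    fig, ax = plt.subplots(figsize=(0.6 * len(cm.r) + 2.5,) * 2)
    im = ax.imshow(cm.r.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cm.r)), [str(c) for c in cm.r.columns], rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.r)), [str(c) for c in cm.r.index], fontsize=7)
    for i in range(len(cm.r)):
        for j in range(len(cm.r)):
            mark = "*" if cm.p.iloc[i, j] < cm.alpha and i != j else ""
            ax.text(j, i, f"{cm.r.iloc[i, j]:.2f}{mark}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    sidecar = cm.r.stack().rename("r").to_frame()
    sidecar["p"] = cm.p.stack()
    sidecar = sidecar.reset_index()
    sidecar.columns = ["feature_a", "feature_b", "r", "p"]
    return fig, sidecar


def _plot_heatmap(request: PlotRequest):
    table = _require(request.table, "a trait table")
    Z = standardize(table.values)
    row_cl = ward_cluster(table, axis="observations")
    col_cl = ward_cluster(table, axis="features")
    ordered = Z.iloc[row_cl.leaf_order, col_cl.leaf_order]
    fig, ax = plt.subplots(figsize=(0.55 * ordered.shape[1] + 2.5, 0.35 * ordered.shape[0] + 2))
    im = ax.imshow(ordered.to_numpy(float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(ordered.shape[1]), [str(c) for c in ordered.columns],
                  rotation=90, fontsize=7)
    ax.set_yticks(range(ordered.shape[0]), _treatment_labels(ordered.index), fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="z-score")
    fig.tight_layout()
    sidecar = ordered.stack().rename("zscore").reset_index()
    sidecar.columns = [*[f"factor{i+1}" for i in range(ordered.index.nlevels)],
                       "feature", "zscore"]
    return fig, sidecar


def _plot_biplot(request: PlotRequest):
    table = _require(request.table, "a trait table")
    pca = pca_correlation(table)
    pts, arrows = pca.biplot_coords()
    fig, ax = plt.subplots(figsize=(6.5, 6))
    ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], color=PALETTE[0], s=28)
    for label, (x, y) in zip(_treatment_labels(pts.index), pts.to_numpy(float)):
        ax.annotate(label, (x, y), fontsize=7, xytext=(3, 3), textcoords="offset points")
    scale = np.abs(pts.to_numpy(float)).max() / max(np.abs(arrows.to_numpy(float)).max(), 1e-12)
    for feat, (x, y) in zip(arrows.index, arrows.to_numpy(float) * scale * 0.85):
        ax.annotate("", (x, y), (0, 0), arrowprops={"arrowstyle": "->", "color": PALETTE[3]})
        ax.annotate(str(feat), (x, y), fontsize=8, color=PALETTE[3])
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"PC1 ({pca.explained.iloc[0]:.1%})")
    ax.set_ylabel(f"PC2 ({pca.explained.iloc[1]:.1%})")
    fig.tight_layout()
    obs = pts.reset_index()
    obs.insert(0, "item_type", "observation")
    obs.columns = ["item_type", *[f"factor{i+1}" for i in range(pts.index.nlevels)], "PC1", "PC2"]
    obs["item"] = _treatment_labels(pts.index)
    feat = arrows.reset_index()
    feat.columns = ["item", "PC1", "PC2"]
    feat.insert(0, "item_type", "feature")
    sidecar = pd.concat([obs[["item_type", "item", "PC1", "PC2"]], feat], ignore_index=True)
    return fig, sidecar


def _plot_ct_qc(request: PlotRequest):
    wells = list(_require(request.wells, "raw Ct wells"))
    frame = pd.DataFrame(
        {
            "gene": [w.gene_id for w in wells],
            "role": [w.role for w in wells],
            "ct": [w.ct for w in wells],
        }
    )
    present = frame.dropna(subset=["ct"])
    genes = list(dict.fromkeys(frame["gene"]))
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(genes)), 4.5))
    data = [present.loc[present["gene"] == g, "ct"].to_numpy() for g in genes]
    ax.boxplot(data, tick_labels=genes)
    ax.tick_params(axis="x", rotation=45)
    ax.set_ylabel("Ct (cycles)")
    ax.set_title("raw Ct distribution per gene")
    fig.tight_layout()
    return fig, frame


_RENDERERS = {
    1: _plot_bars,
    2: _plot_grouped_bars,
    3: _plot_dots,
    4: _plot_box,
    5: _plot_lines,
    6: _plot_radar,
    7: _plot_corr,
    8: _plot_heatmap,
    9: _plot_biplot,
    10: _plot_ct_qc,
}
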