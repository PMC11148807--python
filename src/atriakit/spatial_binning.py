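"""Hexagonal pseudo-spot binning and spot-matrix processing.

Single-molecule spatial transcriptomics (Molecular Cartography-style) yields
one (x, y, gene) record per detected transcript. To analyze such data with
spot-based tooling, molecules are counted into a grid of pointy-top
hexagons 80 px wide (center-to-center horizontal spacing) covering the
whole slide, simulating small high-resolution capture spots. The resulting
pseudo-spot matrix is processed *without* library-size normalization —
targeted panels carry real signal in their totals — while Visium-style spot
matrices follow the standard counts-per-10k recipe. Per-gene signal across
sections is summarized with 1.5*IQR boxplot statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .comparison_stats import BoxplotSummary, boxplot_summary
from .expression_pipeline import (
    PipelineConfig,
    knn_graph,
    leiden_cluster,
    log1p_only,
    normalize_log1p,
    pca_embed,
    regress_covariates,
    scale_clip,
    score_gene_set,
    select_hvg,
)

__all__ = [
    "HexGrid",
    "build_hex_grid",
    "assign_molecules",
    "process_resolve_spots",
    "process_visium_spots",
    "quantify_gene_by_section",
    "export_molecule_map",
]

SQRT3 = np.sqrt(3.0)


@dataclass
class HexGrid:
    """Pointy-top hexagon grid anchored at the bounding-box minimum corner.

    ``width`` is the center-to-center horizontal spacing within a row;
    rows are ``width * sqrt(3)/2`` apart with odd rows offset by half a
    width. ``centers`` enumerates hexagon centers row-major (ascending
    axial r, then q), which defines the tie-break index order.
    """

    width: float
    origin: tuple[float, float]
    centers: np.ndarray  # (n, 2) hexagon centers
    axial: np.ndarray  # (n, 2) integer axial coordinates (q, r)
    index_of: dict[tuple[int, int], int]

    @property
    def size(self) -> float:
        """Center-to-vertex distance."""
        return self.width / SQRT3

    def axial_to_xy(self, q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + self.size * (SQRT3 * q + SQRT3 / 2.0 * r)
        y = self.origin[1] + self.size * 1.5 * r
        return x, y


def build_hex_grid(
    bbox: tuple[float, float, float, float], width: float = 80.0
) -> HexGrid:
    """Hexagon grid covering ``bbox = (xmin, ymin, xmax, ymax)`` with at
    least one hexagon of margin on every side."""
    if width <= 0:
        raise ValueError("hexagon width must be positive")
    xmin, ymin, xmax, ymax = bbox
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate bounding box")
    size = width / SQRT3
    row_step = 1.5 * size  # == width * sqrt(3) / 2
    r_lo = int(np.floor((0 - 2 * row_step) / row_step)) - 1
    r_hi = int(np.ceil((ymax - ymin + 2 * row_step) / row_step)) + 1
    qs, rs = [], []
    for r in range(r_lo, r_hi + 1):
        # x(q) = size*sqrt(3)*(q + r/2); cover [xmin - width, xmax + width]
        q_lo = int(np.floor((-(2 * width)) / width - r / 2.0)) - 1
        q_hi = int(np.ceil((xmax - xmin + 2 * width) / width - r / 2.0)) + 1
        for q in range(q_lo, q_hi + 1):
            qs.append(q)
            rs.append(r)
    axial = np.column_stack([qs, rs])
    grid = HexGrid(
        width=float(width),
        origin=(float(xmin), float(ymin)),
        centers=np.empty((len(axial), 2)),
        axial=axial,
        index_of={},
    )
    x, y = grid.axial_to_xy(axial[:, 0], axial[:, 1])
    grid.centers = np.column_stack([x, y])
    grid.index_of = {(int(q), int(r)): i for i, (q, r) in enumerate(axial)}
    return grid


def _axial_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cube-coordinate rounding of fractional axial coordinates."""
    sf = -qf - rf
    q, r, s = np.round(qf), np.round(rf), np.round(sf)
    dq, dr, ds = np.abs(q - qf), np.abs(r - rf), np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return q.astype(np.int64), r.astype(np.int64)


_NEIGHBOR_OFFSETS = np.array(
    [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]
)


def assign_molecules(molecules: pd.DataFrame, grid: HexGrid) -> ad.AnnData:
    """Count molecules into hexagonal pseudo-spots.

    Each molecule goes to the hexagon containing it (axial rounding,
    verified against the containing hexagon's immediate neighbours so the
    result equals nearest-center assignment; exact distance ties resolve to
    the lowest hexagon index). Empty hexagons are dropped; total counts are
    conserved. Molecules outside the padded grid raise an error listing the
    offenders.
    """
    required = {"x", "y", "gene"}
    if not required <= set(molecules.columns):
        raise ValueError(f"molecule table must have columns {sorted(required)}")
    genes = pd.Index(sorted(molecules["gene"].unique()))
    if len(molecules) == 0:
        return ad.AnnData(
            X=np.zeros((0, 0)),
            obs=pd.DataFrame({"x": pd.Series(dtype=float),
                              "y": pd.Series(dtype=float)}),
            var=pd.DataFrame(index=pd.Index([], name="gene")),
            uns={"platform": "hexbin", "hex_width": grid.width},
        )
    x = molecules["x"].to_numpy(float) - grid.origin[0]
    y = molecules["y"].to_numpy(float) - grid.origin[1]
    size = grid.size
    qf = (SQRT3 / 3.0 * x - y / 3.0) / size
    rf = (2.0 / 3.0 * y) / size
    q0, r0 = _axial_round(qf, rf)

    # nearest-center among the rounded hexagon and its six neighbours,
    # ties to the lowest grid index
    n = len(molecules)
    best_idx = np.full(n, -1, dtype=np.int64)
    best_d2 = np.full(n, np.inf)
    px = molecules["x"].to_numpy(float)
    py = molecules["y"].to_numpy(float)
    for dq, dr in _NEIGHBOR_OFFSETS:
        q, r = q0 + dq, r0 + dr
        idx = np.array(
            [grid.index_of.get((int(qi), int(ri)), -1) for qi, ri in zip(q, r)]
        )
        valid = idx >= 0
        if not valid.any():
            continue
        cx, cy = grid.centers[idx[valid], 0], grid.centers[idx[valid], 1]
        d2 = (px[valid] - cx) ** 2 + (py[valid] - cy) ** 2
        sub = np.flatnonzero(valid)
        closer = d2 < best_d2[sub]
        tied = d2 == best_d2[sub]
        better = closer | (tied & (idx[valid] < best_idx[sub]))
        best_d2[sub[better]] = d2[better]
        best_idx[sub[better]] = idx[valid][better]

    if (best_idx < 0).any():
        offenders = molecules.index[best_idx < 0].tolist()
        raise ValueError(f"molecules outside the padded grid: {offenders[:10]}")

    gene_ix = genes.get_indexer(molecules["gene"])
    used = np.unique(best_idx)
    spot_of = {int(h): i for i, h in enumerate(used)}
    counts = np.zeros((len(used), len(genes)))
    np.add.at(counts, (np.array([spot_of[int(h)] for h in best_idx]), gene_ix), 1.0)
    obs = pd.DataFrame(
        {
            "x": grid.centers[used, 0],
            "y": grid.centers[used, 1],
            "hex_q": grid.axial[used, 0],
            "hex_r": grid.axial[used, 1],
        },
        index=[f"hex_{grid.axial[h, 0]}_{grid.axial[h, 1]}" for h in used],
    )
    if "section" in molecules.columns:
        obs["section"] = molecules["section"].iloc[0]
    return ad.AnnData(
        X=counts, obs=obs, var=pd.DataFrame(index=genes),
        uns={"platform": "hexbin", "hex_width": grid.width},
    )


def process_resolve_spots(
    spots: ad.AnnData,
    n_pcs: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 10,
    batch_hook: Callable | None = None,
) -> dict:
    """Processing recipe for hex-binned targeted-panel pseudo-spots.

    Counts are logarithmized without library-size normalization (small
    targeted panels make totals biological); per-gene regression then
    removes the global effect of per-spot total counts and detected-gene
    counts; scaling (clip 10), PCA on the top ``n_pcs``, optional
    per-section batch hook, kNN and seeded Leiden follow.
    """
    if spots.n_vars < 2:
        raise ValueError("need at least 2 genes to process pseudo-spots")
    norm = log1p_only(spots)
    covs = {
        "total_counts": norm.cell_meta["total_counts"].to_numpy(float),
        "n_genes": norm.cell_meta["n_genes"].to_numpy(float),
    }
    residual = regress_covariates(norm, covs)
    scaled = scale_clip(residual, 10.0)
    embedding = pca_embed(scaled, n_pcs)
    if batch_hook is not None:
        embedding = batch_hook(embedding, norm.cell_meta.get("section"))
    graph = knn_graph(embedding, n_neighbors)
    labels = leiden_cluster(graph, resolution, seed)
    return {"normalized": norm, "embedding": embedding, "graph": graph,
            "labels": labels}


def process_visium_spots(
    spots: ad.AnnData,
    marker_sets: Mapping[str, Sequence[str]] | None = None,
    target: float = 10_000.0,
    n_pcs: int = 40,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 10,
    mito_prefix: str = "MT-",
    batch_hook: Callable | None = None,
    hvg_kwargs: dict | None = None,
) -> dict:
    """Processing recipe for Visium-style spot matrices.

    Counts are normalized to ``target`` per capture area and logarithmized;
    highly variable genes are selected with the snRNA cutoffs; total counts
    and mitochondrial percentage are regressed out; scaling (clip 10), PCA,
    optional batch hook, kNN and Leiden follow. When ``marker_sets`` are
    supplied (snRNA-derived cell-type markers), per-spot cell-type scores
    are computed on the full normalized matrix.
    """
    norm = normalize_log1p(spots, target)
    mito = [g for g in norm.genes if str(g).startswith(mito_prefix)]
    x_counts = np.expm1(norm.values) * (
        norm.cell_meta["total_counts"].to_numpy(float)[:, None] / target
    )
    pct_mito = (
        x_counts[:, norm.genes.get_indexer(mito)].sum(axis=1)
        / np.maximum(x_counts.sum(axis=1), 1e-12) * 100.0
        if mito else np.zeros(len(norm.cell_meta))
    )
    hvg = select_hvg(norm, **(hvg_kwargs or {}))
    sub = norm.subset_genes(hvg)
    covs = {
        "total_counts": sub.cell_meta["total_counts"].to_numpy(float),
        "pct_mito": np.asarray(pct_mito, float),
    }
    if np.ptp(covs["pct_mito"]) == 0:
        covs.pop("pct_mito")
    residual = regress_covariates(sub, covs)
    scaled = scale_clip(residual, 10.0)
    embedding = pca_embed(scaled, n_pcs)
    if batch_hook is not None:
        embedding = batch_hook(embedding, sub.cell_meta.get("section"))
    graph = knn_graph(embedding, n_neighbors)
    labels = leiden_cluster(graph, resolution, seed)
    result = {"normalized": norm, "hvg_mask": hvg, "embedding": embedding,
              "graph": graph, "labels": labels}
    if marker_sets:
        result["celltype_scores"] = pd.DataFrame(
            {name: score_gene_set(norm, genes, seed=seed)
             for name, genes in marker_sets.items()},
            index=norm.cells,
        )
    return result


def quantify_gene_by_section(
    sections: Sequence[ad.AnnData],
    gene: str,
    section_ids: Sequence[str] | None = None,
    groups: Mapping[str, str] | None = None,
    normalize: bool = True,
    target: float = 10_000.0,
) -> dict:
    """Per-section distribution summary of one gene's per-spot expression.

    Expression is the normalized-log value (ln(CP-``target``+1), or plain
    log1p when ``normalize`` is False); each section is summarized with the
    1.5*IQR boxplot rule. Sections lacking the gene in their panel are
    reported as missing, never as zero. When ``groups`` maps section id to
    group, pooled per-group summaries are added.
    """
    if section_ids is None:
        section_ids = [f"section{i + 1}" for i in range(len(sections))]
    per_section: dict[str, BoxplotSummary | None] = {}
    values_of: dict[str, np.ndarray] = {}
    for sid, adata in zip(section_ids, sections):
        if gene not in adata.var_names:
            per_section[sid] = None
            continue
        norm = normalize_log1p(adata, target) if normalize else log1p_only(adata)
        v = norm.values[:, norm.genes.get_loc(gene)]
        values_of[sid] = v
        per_section[sid] = boxplot_summary(v)
    out = {"gene": gene, "per_section": per_section}
    if groups is not None:
        by_group: dict[str, list[np.ndarray]] = {}
        for sid, v in values_of.items():
            grp = groups.get(sid)
            if grp is not None:
                by_group.setdefault(grp, []).append(v)
        out["per_group"] = {
            grp: boxplot_summary(np.concatenate(vs)) for grp, vs in by_group.items()
        }
    return out


def export_molecule_map(
    molecules: pd.DataFrame,
    palette: Mapping[str, str],
    csv_path: str | None = None,
    png_path: str | None = None,
    default_color: str = "#b0b0b0",
    point_size: float = 1.0,
) -> pd.DataFrame:
    """Per-molecule dot map: one point per molecule at its exact location,
    colored by gene. Genes missing from the palette get the default color.
    Optionally written as CSV (x, y, gene, color) and/or rendered to PNG."""
    table = molecules[["x", "y", "gene"]].copy()
    table["color"] = table["gene"].map(lambda g: palette.get(g, default_color))
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 8))
        ax.scatter(table["x"], table["y"], c=table["color"], s=point_size,
                   linewidths=0)
        ax.set_aspect("equal")
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        fig.savefig(png_path, dpi=200)
        plt.close(fig)
    return table
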