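"""Deterministic single-nuclei expression-processing chain.

The stages mirror the standard snRNA-seq recipe used for cardiac tissue
atlases: rare-gene filtering, library-size normalization to ln(CP10K+1),
dispersion-based highly-variable-gene selection, per-gene linear regression
against nuisance covariates, standard scaling with clipping, PCA, a
k-nearest-neighbour graph, and Leiden clustering — followed by marker
scoring against expression-matched control genes, Wilcoxon marker ranking
with Benjamini-Hochberg correction, marker-based cluster annotation with
doublet-cluster flagging, and per-sample composition tables.

Batch integration and 2-D embedding are published external algorithms and
are exposed only as hook stages (`batch_hook` after PCA, `embed_hook` after
the kNN graph) with identity defaults, preserving the stage order
PCA -> batch hook -> kNN -> clustering / embedding hook.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparison_stats import boxplot_summary

__all__ = [
    "ProcessedMatrix",
    "PipelineConfig",
    "filter_rare_genes",
    "normalize_log1p",
    "select_hvg",
    "regress_covariates",
    "scale_clip",
    "pca_embed",
    "knn_graph",
    "leiden_cluster",
    "score_gene_set",
    "rank_markers",
    "annotate_clusters",
    "compute_proportions",
    "run_snrna_pipeline",
]

_STAGES = ("raw", "normalized_log", "residual", "scaled")


@dataclass
class ProcessedMatrix:
    """Cells x genes real matrix at a named processing stage.

    Stages advance only forward through raw -> normalized_log -> residual ->
    scaled; each operation returns a new object at the next stage.
    """

    values: np.ndarray
    stage: str
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise ValueError("values shape does not match metadata")

    @property
    def genes(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def cells(self) -> pd.Index:
        return self.cell_meta.index

    def advanced(self, values: np.ndarray, stage: str, **meta) -> "ProcessedMatrix":
        if _STAGES.index(stage) < _STAGES.index(self.stage):
            raise ValueError(f"stage cannot move backwards: {self.stage} -> {stage}")
        return ProcessedMatrix(
            values=values,
            stage=stage,
            cell_meta=meta.get("cell_meta", self.cell_meta),
            gene_meta=meta.get("gene_meta", self.gene_meta),
        )

    def subset_genes(self, mask: np.ndarray) -> "ProcessedMatrix":
        return ProcessedMatrix(
            self.values[:, mask], self.stage,
            self.cell_meta, self.gene_meta.loc[mask],
        )


@dataclass
class PipelineConfig:
    """Defaults of the snRNA-seq processing chain."""

    min_cells: int = 10
    norm_target: float = 10_000.0
    hvg_min_mean: float = 0.0125
    hvg_max_mean: float = 3.0
    hvg_min_disp: float = 0.5
    hvg_n_bins: int = 20
    scale_max: float = 10.0
    n_pcs: int = 40
    n_neighbors: int = 10
    leiden_resolution: float = 1.0
    score_n_bins: int = 25
    score_n_ctrl: int = 50
    seed: int = 0


def _dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_rare_genes(counts: ad.AnnData, min_cells: int = 10) -> ad.AnnData:
    """Drop genes detected (count > 0) in fewer than ``min_cells`` cells."""
    if counts.n_obs == 0 or counts.n_vars == 0:
        raise ValueError("empty count matrix")
    x = _dense(counts.X)
    detected = (x > 0).sum(axis=0)
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError("all genes filtered out; no gene detected in enough cells")
    return counts[:, keep].copy()


def normalize_log1p(counts: ad.AnnData, target: float = 10_000.0) -> ProcessedMatrix:
    """ln(counts-per-``target`` + 1) normalization.

    Cells with zero total counts are dropped with a warning; the
    back-transformed row sums of the result equal ``target`` exactly (up to
    float round-off).
    """
    x = _dense(counts.X)
    if (x < 0).any():
        raise ValueError("negative counts")
    totals = x.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} zero-count cells",
                      stacklevel=2)
        x, totals = x[nonzero], totals[nonzero]
        counts = counts[nonzero]
    values = np.log1p(x * (target / totals[:, None]))
    gene_meta = counts.var.copy()
    cell_meta = counts.obs.copy()
    cell_meta["total_counts"] = totals
    cell_meta["n_genes"] = (x > 0).sum(axis=1)
    return ProcessedMatrix(values, "normalized_log", cell_meta, gene_meta)


def log1p_only(counts: ad.AnnData) -> ProcessedMatrix:
    """log1p of raw counts without library-size normalization.

    Used for sparse targeted panels where per-spot totals are biological
    signal rather than depth; the ``normalized_log`` stage name is reused so
    downstream stages compose, but row sums are deliberately not equalized.
    """
    x = _dense(counts.X)
    if (x < 0).any():
        raise ValueError("negative counts")
    cell_meta = counts.obs.copy()
    cell_meta["total_counts"] = x.sum(axis=1)
    cell_meta["n_genes"] = (x > 0).sum(axis=1)
    return ProcessedMatrix(np.log1p(x), "normalized_log", cell_meta, counts.var.copy())


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

def select_hvg(
    norm: ProcessedMatrix,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = 0.5,
    n_bins: int = 20,
    log_mean: bool = False,
) -> np.ndarray:
    """Dispersion-based highly-variable-gene mask.

    Mean and dispersion (variance/mean) are computed on the back-transformed
    (expm1) scale of the log-normalized data; dispersions are z-scored
    within ``n_bins`` equal-frequency mean bins; a gene passes iff
    ``min_mean < mean < max_mean`` and normalized dispersion >= ``min_disp``.
    Singleton bins (SD undefined) are merged with their left neighbour so no
    gene is silently dropped. With ``log_mean=True`` the cutoffs are applied
    to the log-scale mean instead.
    """
    if norm.stage != "normalized_log":
        raise ValueError("select_hvg expects the normalized_log stage")
    g = norm.values.shape[1]
    if g < 2:
        raise ValueError("need at least 2 genes")
    back = np.expm1(norm.values)
    mean = back.mean(axis=0)
    var = back.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    n_bins = min(n_bins, g)
    # equal-frequency bins of the mean; stable argsort fixes tie order
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(g, dtype=np.int64)
    bin_of[order] = np.floor(np.arange(g) * n_bins / g).astype(np.int64)
    # merge singleton bins leftwards so every bin has >= 2 members
    for b in range(n_bins):
        members = bin_of == b
        if 0 < members.sum() < 2:
            bin_of[members] = max(b - 1, 0) if b > 0 else b + 1

    disp_norm = np.zeros(g)
    for b in np.unique(bin_of):
        members = bin_of == b
        mu, sd = disp[members].mean(), disp[members].std()
        disp_norm[members] = 0.0 if sd < 1e-12 else (disp[members] - mu) / sd

    mean_for_cutoff = np.log1p(mean) if log_mean else mean
    mask = (
        (mean_for_cutoff > min_mean)
        & (mean_for_cutoff < max_mean)
        & (disp_norm >= min_disp)
    )
    norm.gene_meta["mean"] = mean
    norm.gene_meta["dispersion"] = disp
    norm.gene_meta["dispersion_norm"] = disp_norm
    norm.gene_meta["highly_variable"] = mask
    return mask


# ---------------------------------------------------------------------------
# regression, scaling, PCA
# ---------------------------------------------------------------------------

def regress_covariates(
    norm: ProcessedMatrix, covariates: Mapping[str, np.ndarray]
) -> ProcessedMatrix:
    """Per-gene OLS regression on nuisance covariates; residuals returned.

    An intercept is always included; constant covariates are dropped with a
    warning (collinear with the intercept).
    """
    n = norm.values.shape[0]
    cols, names = [np.ones(n)], ["intercept"]
    for name, vec in covariates.items():
        v = np.asarray(vec, dtype=float)
        if v.shape != (n,):
            raise ValueError(f"covariate {name!r} has wrong length")
        if not np.isfinite(v).all():
            raise ValueError(f"covariate {name!r} contains non-finite values")
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=2)
            continue
        cols.append(v)
        names.append(name)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, norm.values, rcond=None)
    residuals = norm.values - design @ beta
    return norm.advanced(residuals, "residual")


def scale_clip(residual: ProcessedMatrix, max_value: float = 10.0) -> ProcessedMatrix:
    """Per-gene standardization (zero mean, unit variance) clipped above at
    ``max_value``; zero-variance genes become all zeros."""
    x = residual.values
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    scaled = (x - mu) / safe
    scaled[:, sd == 0] = 0.0
    return residual.advanced(np.minimum(scaled, max_value), "scaled")


def pca_embed(scaled: ProcessedMatrix | np.ndarray, n_pcs: int = 40) -> np.ndarray:
    """Top principal components, deterministic up to a fixed sign convention
    (the largest-magnitude loading of each component is made positive)."""
    x = scaled.values if isinstance(scaled, ProcessedMatrix) else np.asarray(scaled)
    x = x - x.mean(axis=0)
    max_pcs = min(x.shape)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} clamped to {max_pcs}", stacklevel=2)
        n_pcs = max_pcs
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    signs = np.sign(vt[np.arange(n_pcs), np.abs(vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return (u * s) * signs


def knn_graph(embedding: np.ndarray, k: int = 10) -> sp.csr_matrix:
    """Union-symmetrized k-nearest-neighbour graph (Euclidean).

    Ties in distance are broken by lower cell index; the returned sparse
    adjacency has weight 1 on every undirected edge.
    """
    n = embedding.shape[0]
    if k >= n:
        warnings.warn(f"k={k} clamped to n-1={n - 1}", stacklevel=2)
        k = n - 1
    rows, cols = [], []
    chunk = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, chunk):
        block = embedding[start : start + chunk]
        d2 = (
            (block**2).sum(axis=1)[:, None]
            - 2.0 * block @ embedding.T
            + (embedding**2).sum(axis=1)[None, :]
        )
        for i_local in range(block.shape[0]):
            i = start + i_local
            d = d2[i_local].copy()
            d[i] = np.inf
            nn = np.argsort(d, kind="stable")[:k]  # stable sort = index tie-break
            rows.extend([i] * k)
            cols.extend(nn.tolist())
    a = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    sym = a.maximum(a.T)
    sym.data[:] = 1.0
    return sym


def leiden_cluster(
    graph: sp.spmatrix | igraph.Graph, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection (RBConfiguration objective), seeded.

    Labels are relabeled to descending cluster size (ties by lower original
    label).
    """
    g = _as_igraph(graph)
    if g.vcount() == 0:
        raise ValueError("empty graph")
    weights = g.es["weight"] if "weight" in g.es.attributes() else None
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
    )
    return relabel_by_size(np.asarray(part.membership))


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel integer labels to descending count (ties: lower original)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    mapping = {int(uniq[i]): rank for rank, i in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels], dtype=np.int64)


def _as_igraph(graph) -> igraph.Graph:
    if isinstance(graph, igraph.Graph):
        return graph
    coo = sp.triu(sp.coo_matrix(graph), k=1)
    g = igraph.Graph(n=graph.shape[0],
                     edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    g.es["weight"] = coo.data.tolist()
    return g


# ---------------------------------------------------------------------------
# scoring, marker ranking, annotation
# ---------------------------------------------------------------------------

def score_gene_set(
    norm: ProcessedMatrix,
    gene_set: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell gene-set score against expression-matched controls.

    All genes are binned by mean expression into ``n_bins`` equal-frequency
    bins; for each set gene, up to ``n_ctrl`` control genes are sampled
    (seeded, without replacement) from its bin, excluding set members. The
    score is mean(set genes) - mean(control genes) per cell, so a matrix
    where all genes are identically distributed scores ~0.
    """
    genes = norm.genes
    present = [g for g in gene_set if g in genes]
    dropped = len(list(gene_set)) - len(present)
    if dropped:
        warnings.warn(f"{dropped} gene-set members absent from the matrix",
                      stacklevel=2)
    if not present:
        raise ValueError("gene set empty after intersecting with the gene axis")
    rng = np.random.default_rng(seed)
    gene_ix = {g: i for i, g in enumerate(genes)}
    set_ix = np.array([gene_ix[g] for g in present])
    mean = norm.values.mean(axis=0)
    g = len(genes)
    n_bins = min(n_bins, g)
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(g, dtype=np.int64)
    bin_of[order] = np.floor(np.arange(g) * n_bins / g).astype(np.int64)

    in_set = np.zeros(g, bool)
    in_set[set_ix] = True
    ctrl: set[int] = set()
    for i in set_ix:
        pool = np.flatnonzero((bin_of == bin_of[i]) & ~in_set)
        if pool.size == 0:
            pool = np.flatnonzero(bin_of == bin_of[i])
        take = min(n_ctrl, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_ix = np.array(sorted(ctrl))
    return norm.values[:, set_ix].mean(axis=1) - norm.values[:, ctrl_ix].mean(axis=1)


def rank_markers(
    norm: ProcessedMatrix,
    labels: np.ndarray,
    n_top: int = 500,
    alpha: float = 0.05,
    exact_below: int = 25,
) -> dict[int, pd.DataFrame]:
    """Per-cluster Wilcoxon rank-sum marker tables with BH correction.

    For each cluster, a two-sided rank-sum test of cluster vs rest is run
    per gene (normal approximation with tie correction; exact enumeration
    when both group sizes are below ``exact_below`` and ties allow).
    P-values are BH-corrected across genes within the cluster; the table is
    sorted by (p-value, descending logFC) and truncated to the first
    ``n_top`` significant genes. logFC is the difference of mean
    log-normalized expression (cluster - rest).
    """
    labels = np.asarray(labels)
    out: dict[int, pd.DataFrame] = {}
    x = norm.values
    for lab in np.unique(labels):
        in_c = labels == lab
        n1, n2 = int(in_c.sum()), int((~in_c).sum())
        if n1 < 2 or n2 < 2:
            warnings.warn(f"cluster {lab} too small for testing; skipped",
                          stacklevel=2)
            continue
        method = "auto" if max(n1, n2) < exact_below else "asymptotic"
        res = stats.mannwhitneyu(
            x[in_c], x[~in_c], axis=0, alternative="two-sided", method=method
        )
        pvals = np.atleast_1d(res.pvalue)
        logfc = x[in_c].mean(axis=0) - x[~in_c].mean(axis=0)
        fdr = benjamini_hochberg(pvals)
        sig = fdr < alpha
        table = pd.DataFrame(
            {"gene": norm.genes, "logFC": logfc, "pvalue": pvals,
             "fdr": fdr, "significant": sig}
        )
        table = table.sort_values(
            ["pvalue", "logFC"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
        out[int(lab)] = table[table["significant"]].head(n_top).reset_index(drop=True)
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def annotate_clusters(
    norm: ProcessedMatrix,
    labels: np.ndarray,
    reference_markers: Mapping[str, Sequence[str]],
    high_quantile: float = 0.9,
    doublet_ratio: float = 0.4,
    score_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Marker-score cluster annotation with doublet-cluster flagging.

    Each cluster's mean marker score is computed per reference type and the
    cluster is assigned the argmax type. A cluster is flagged as a doublet
    cluster when it expresses the markers of two or more distinct types at
    a high level: a type counts as "high" when its score is positive,
    exceeds the ``high_quantile`` quantile of the pooled off-target scores
    (cluster/type pairs where the type is not that cluster's best match),
    and is at least ``doublet_ratio`` of the cluster's own best score —
    the last condition separates genuine co-expression from mild off-target
    leakage.
    """
    if not reference_markers:
        raise ValueError("no reference marker sets provided")
    labels = np.asarray(labels)
    types = list(reference_markers)
    kw = score_kwargs or {}
    per_cell = {t: score_gene_set(norm, reference_markers[t], **kw) for t in types}
    clusters = np.unique(labels)
    score = np.array(
        [[per_cell[t][labels == c].mean() for t in types] for c in clusters]
    )
    best = score.argmax(axis=1)
    off_target = np.concatenate(
        [np.delete(score[i], best[i]) for i in range(len(clusters))]
    ) if len(types) > 1 else np.array([])
    doublet = np.zeros(len(clusters), bool)
    if off_target.size:
        threshold = np.quantile(off_target, high_quantile)
        best_score = score.max(axis=1, keepdims=True)
        high = (score > 0) & (score > threshold) & (
            score >= doublet_ratio * np.maximum(best_score, 0)
        )
        doublet = high.sum(axis=1) >= 2
    return pd.DataFrame(
        {
            "cluster": clusters,
            "cell_type": [types[b] for b in best],
            "doublet_cluster": doublet,
            **{f"score_{t}": score[:, j] for j, t in enumerate(types)},
        }
    ).set_index("cluster")


def compute_proportions(
    labels: np.ndarray,
    sample_ids: np.ndarray,
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-sample percentage of cells per label, plus per-group boxplot
    summaries of those percentages.

    ``groups`` maps sample id to group name; samples with zero cells are
    excluded with a warning. Each sample's proportions sum to 100.
    """
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    if labels.shape != sample_ids.shape:
        raise ValueError("labels and sample_ids length mismatch")
    df = pd.DataFrame({"label": labels, "sample": sample_ids})
    table = (
        df.groupby(["sample", "label"], observed=True).size().unstack(fill_value=0)
    )
    totals = table.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"excluding empty samples: {list(table.index[empty])}",
                      stacklevel=2)
        table = table[~empty]
        totals = totals[~empty]
    pct = table.div(totals, axis=0) * 100.0
    summaries: dict = {}
    if groups is not None:
        group_of = pct.index.map(lambda s: groups.get(s))
        for grp in sorted({g for g in group_of if g is not None}):
            rows = pct[group_of == grp]
            summaries[grp] = {
                lab: boxplot_summary(rows[lab].to_numpy()) for lab in pct.columns
            }
    return pct, summaries


# ---------------------------------------------------------------------------
# end-to-end chain
# ---------------------------------------------------------------------------

def run_snrna_pipeline(
    counts: ad.AnnData,
    config: PipelineConfig | None = None,
    covariates: Mapping[str, np.ndarray] | None = None,
    batch_hook: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    embed_hook: Callable[[sp.spmatrix], np.ndarray] | None = None,
) -> dict:
    """Filter -> normalize -> HVG -> regress -> scale -> PCA -> batch hook ->
    kNN -> Leiden, returning every intermediate needed downstream.

    ``covariates`` defaults to per-cell total counts (and mitochondrial
    percentage when a ``pct_mito`` column is present in ``counts.obs``).
    Hooks default to identity; they are the integration points for external
    batch correction and 2-D embedding.
    """
    cfg = config or PipelineConfig()
    filtered = filter_rare_genes(counts, cfg.min_cells)
    norm = normalize_log1p(filtered, cfg.norm_target)
    hvg = select_hvg(
        norm, cfg.hvg_min_mean, cfg.hvg_max_mean, cfg.hvg_min_disp, cfg.hvg_n_bins
    )
    sub = norm.subset_genes(hvg)
    if covariates is None:
        covariates = {"total_counts": sub.cell_meta["total_counts"].to_numpy(float)}
        if "pct_mito" in sub.cell_meta:
            covariates["pct_mito"] = sub.cell_meta["pct_mito"].to_numpy(float)
    residual = regress_covariates(sub, covariates)
    scaled = scale_clip(residual, cfg.scale_max)
    embedding = pca_embed(scaled, cfg.n_pcs)
    if batch_hook is not None:
        embedding = batch_hook(embedding, sub.cell_meta.get("sample"))
    graph = knn_graph(embedding, cfg.n_neighbors)
    labels = leiden_cluster(graph, cfg.leiden_resolution, cfg.seed)
    result = {
        "normalized": norm,
        "hvg_mask": hvg,
        "scaled": scaled,
        "embedding": embedding,
        "graph": graph,
        "labels": labels,
        "config": replace(cfg),
    }
    if embed_hook is not None:
        result["embedding_2d"] = embed_hook(graph)
    return result
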