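"""Multi-resolution gene co-expression module detection.

Naive gene-gene Pearson correlation in single-cell data is confounded by
cell-cell correlation structure (shared depth, cell states). Zero-phase
component analysis (ZCA) whitening removes that structure while staying
maximally close to the original data. Writing the thin SVD of the centered
cells x genes matrix as X = U S V^T, the gene-gene correlation of the
ZCA-whitened matrix is proportional to V S^P V^T with P = 0; P = 2 recovers
the ordinary Pearson correlation (X^T X = V S^2 V^T), and intermediate
exponents interpolate. The detector evaluates several resolutions P,
z-scores each correlation matrix within strata of gene sparsity (number of
zeros in the raw count matrix), keeps edges with z above a threshold, and
runs multiplex Leiden community detection across the per-resolution graphs
to produce one consistent set of gene modules.

Defaults follow the published recipe: P in {0, 0.5, 1}, edge threshold
z > 4.5, Leiden resolution 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats

from .expression_pipeline import (
    ProcessedMatrix,
    benjamini_hochberg,
    relabel_by_size,
    score_gene_set,
)

__all__ = [
    "ZcaCorrelation",
    "ModuleSet",
    "zca_gene_correlation",
    "sparsity_zscore",
    "threshold_graph",
    "multigraph_leiden",
    "detect_modules",
    "score_modules",
    "enrich_modules",
]

#: singular values below this times the largest are treated as numerical
#: null space: their contribution is dropped at every P (0**0 := 0).
_RANK_RTOL = 1e-12


@dataclass
class ZcaCorrelation:
    """Gene-gene correlation V S^P V^T normalized to unit diagonal."""

    P: float
    C: np.ndarray
    S: np.ndarray
    V: np.ndarray  # genes x rank right singular vectors
    undefined: np.ndarray  # genes whose diagonal was zero (correlations set 0)
    U: np.ndarray | None = None


@dataclass
class ModuleSet:
    """Disjoint gene modules with the evidence that produced them."""

    modules: list[list[str]]
    gene_names: list[str]
    module_of_gene: np.ndarray  # -1 for unassigned genes
    params: dict = field(default_factory=dict)
    edges_per_resolution: dict[float, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            overlap = seen & set(mod)
            if overlap:
                raise ValueError(f"modules not disjoint: {sorted(overlap)[:5]}")
            seen |= set(mod)
        unknown = seen - set(self.gene_names)
        if unknown:
            raise ValueError(f"module genes absent from gene axis: {sorted(unknown)[:5]}")


def zca_gene_correlation(
    X: np.ndarray, P: float, keep_U: bool = False
) -> ZcaCorrelation:
    """Gene-gene correlation at resolution P from the SVD of centered X.

    The raw matrix M = V S^P V^T is normalized to correlation scale by its
    diagonal, C = D^{-1/2} M D^{-1/2}. P = 0 reproduces the correlation of
    the explicitly ZCA-whitened matrix (X X^T)^{-1/2} X; P = 2 reproduces
    the Pearson correlation of X. Genes whose diagonal vanishes (outside
    the retained rank space) get zero correlations and are flagged.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in the expression matrix")
    if min(X.shape) < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > _RANK_RTOL * s[0] if s[0] > 0 else np.zeros_like(s, bool)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    v = vt.T
    m = (v * s**P) @ v.T
    m = (m + m.T) / 2.0
    d = np.diag(m).copy()
    undefined = d <= _RANK_RTOL
    inv_sqrt = np.where(undefined, 0.0, 1.0 / np.sqrt(np.where(undefined, 1.0, d)))
    c = m * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(c, np.where(undefined, 0.0, 1.0))
    return ZcaCorrelation(
        P=float(P), C=c, S=s, V=v, undefined=undefined, U=u if keep_U else None
    )


def sparsity_zscore(
    corr: ZcaCorrelation | np.ndarray,
    zeros_per_gene: np.ndarray,
    n_sparsity_bins: int = 10,
    tie_break: Sequence | None = None,
) -> np.ndarray:
    """Z-score correlations within strata of gene sparsity.

    Genes are placed into equal-frequency bins of their zero count in the
    raw count matrix; for each unordered bin pair, the null mean and SD are
    estimated from all off-diagonal entries between the bins, and each entry
    is standardized against its stratum. This controls for the inflated
    correlation noise of sparse genes. The diagonal is left at 0; strata
    with vanishing spread score 0 with a warning.
    """
    c = corr.C if isinstance(corr, ZcaCorrelation) else np.asarray(corr, float)
    g = c.shape[0]
    zeros_per_gene = np.asarray(zeros_per_gene)
    if zeros_per_gene.shape != (g,):
        raise ValueError("zeros_per_gene not aligned with the gene axis")
    n_bins = n_sparsity_bins
    if g < n_bins:
        warnings.warn(f"only {g} genes; reducing sparsity bins to {g}", stacklevel=2)
        n_bins = g
    if tie_break is not None:
        # secondary key (e.g. gene names) keeps the equal-frequency binning
        # invariant under permutations of the gene axis
        order = np.lexsort((np.asarray(tie_break), zeros_per_gene))
    else:
        order = np.argsort(zeros_per_gene, kind="stable")
    bin_of = np.empty(g, dtype=np.int64)
    bin_of[order] = np.floor(np.arange(g) * n_bins / g).astype(np.int64)

    z = np.zeros_like(c)
    eye = np.eye(g, dtype=bool)
    for a in range(n_bins):
        ia = bin_of == a
        if not ia.any():
            continue
        for b in range(a, n_bins):
            ib = bin_of == b
            if not ib.any():
                continue
            pair_mask = np.outer(ia, ib) | np.outer(ib, ia)
            pair_mask &= ~eye
            entries = c[pair_mask]
            if entries.size == 0:
                continue
            mu, sd = entries.mean(), entries.std()
            if sd < 1e-12:
                warnings.warn(
                    f"sparsity stratum ({a},{b}) has no spread; z set to 0",
                    stacklevel=2)
                continue
            z[pair_mask] = (c[pair_mask] - mu) / sd
    np.fill_diagonal(z, 0.0)
    return z


def threshold_graph(z: np.ndarray, z_min: float = 4.5,
                    gene_names: Sequence[str] | None = None) -> igraph.Graph:
    """Weighted gene graph with an edge wherever z is strictly above
    ``z_min``; isolated genes are retained as nodes."""
    z = np.asarray(z, float)
    g = z.shape[0]
    iu, ju = np.triu_indices(g, k=1)
    sel = z[iu, ju] > z_min
    graph = igraph.Graph(
        n=g, edges=list(zip(iu[sel].tolist(), ju[sel].tolist()))
    )
    graph.es["weight"] = z[iu[sel], ju[sel]].tolist()
    graph.vs["name"] = (
        list(gene_names) if gene_names is not None else [str(i) for i in range(g)]
    )
    return graph


def multigraph_leiden(
    graphs: Sequence[igraph.Graph],
    resolution: float = 2.0,
    seed: int = 0,
    min_module_size: int = 2,
    params: dict | None = None,
) -> ModuleSet:
    """Multiplex Leiden over per-resolution graphs sharing one gene set.

    Optimizes the equally-weighted sum of per-layer RBConfiguration quality.
    Communities smaller than ``min_module_size`` are discarded (their genes
    stay unassigned); modules are ordered by size descending with sorted
    gene lists.
    """
    if not graphs:
        raise ValueError("no graphs provided")
    names = graphs[0].vs["name"]
    for gr in graphs[1:]:
        if gr.vs["name"] != names:
            raise ValueError("graphs do not share a common node set")
    membership, _ = leidenalg.find_partition_multiplex(
        list(graphs),
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    membership = relabel_by_size(np.asarray(membership))
    module_of_gene = np.full(len(names), -1, dtype=np.int64)
    modules: list[list[str]] = []
    for lab in range(membership.max() + 1):
        ix = np.flatnonzero(membership == lab)
        if ix.size < min_module_size:
            continue
        module_of_gene[ix] = len(modules)
        modules.append(sorted(names[i] for i in ix))
    return ModuleSet(
        modules=modules,
        gene_names=list(names),
        module_of_gene=module_of_gene,
        params=dict(params or {}, resolution=resolution,
                    min_module_size=min_module_size, seed=seed),
    )


def detect_modules(
    X: np.ndarray,
    raw_counts: np.ndarray,
    gene_names: Sequence[str] | None = None,
    P_list: Sequence[float] = (0.0, 0.5, 1.0),
    z_min: float = 4.5,
    resolution: float = 2.0,
    seed: int = 0,
    min_module_size: int = 2,
    n_sparsity_bins: int = 10,
) -> ModuleSet:
    """Full module-detection recipe across resolutions.

    ``X`` is the (log-normalized) expression matrix used for the SVD;
    ``raw_counts`` supplies the per-gene zero counts for sparsity
    stratification (sparsity is only meaningful pre-transformation). Both
    must share the gene axis.
    """
    X = np.asarray(X, float)
    raw = np.asarray(raw_counts)
    if raw.shape[1] != X.shape[1]:
        raise ValueError("X and raw_counts gene axes differ")
    if gene_names is None:
        gene_names = [f"G{j:05d}" for j in range(X.shape[1])]
    zeros_per_gene = (raw == 0).sum(axis=0)
    graphs, edge_tables = [], {}
    for P in P_list:
        corr = zca_gene_correlation(X, P)
        z = sparsity_zscore(corr, zeros_per_gene, n_sparsity_bins,
                            tie_break=gene_names)
        graph = threshold_graph(z, z_min, gene_names)
        graphs.append(graph)
        edge_tables[float(P)] = pd.DataFrame(
            {
                "gene_i": [gene_names[e.source] for e in graph.es],
                "gene_j": [gene_names[e.target] for e in graph.es],
                "P": float(P),
                "z": graph.es["weight"] if graph.ecount() else [],
            }
        )
    result = multigraph_leiden(
        graphs, resolution=resolution, seed=seed,
        min_module_size=min_module_size,
        params={"P_list": [float(p) for p in P_list], "z_min": z_min,
                "n_sparsity_bins": n_sparsity_bins},
    )
    result.edges_per_resolution = edge_tables
    return result


def score_modules(
    norm: ProcessedMatrix, module_set: ModuleSet, seed: int = 0, **score_kwargs
) -> pd.DataFrame:
    """Per-cell score of every module via the binned control-gene scorer."""
    if not module_set.modules:
        raise ValueError("empty module set")
    scores = {
        f"module_{m}": score_gene_set(norm, genes, seed=seed + m, **score_kwargs)
        for m, genes in enumerate(module_set.modules)
    }
    return pd.DataFrame(scores, index=norm.cells)


def enrich_modules(
    module_set: ModuleSet,
    sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of annotation sets in each module.

    For a universe of N genes, an annotation set of K genes and a module of
    n genes overlapping in k, the one-sided upper-tail p-value is
    P(X >= k) under Hypergeometric(N, K, n). BH correction runs across all
    module x set pairs. Annotation sets are intersected with the universe.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    rows = []
    for m, genes in enumerate(module_set.modules):
        mod = set(genes) & uni
        for name, members in sets.items():
            ann = set(members) & uni
            k = len(mod & ann)
            p = float(stats.hypergeom.sf(k - 1, len(uni), len(ann), len(mod)))
            rows.append(
                {"module": m, "set": name, "module_size": len(mod),
                 "set_size": len(ann), "overlap": k,
                 "pvalue": min(p, 1.0),
                 "overlap_genes": ",".join(sorted(mod & ann))}
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = benjamini_hochberg(table["pvalue"].to_numpy())
    else:
        table["fdr"] = []
    return table
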