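"""Quality-space droplet filtering for single-nuclei RNA-seq.

Empty droplets in nuclei preparations are dominated by cytoplasmic ambient
RNA: their transcripts are mostly spliced, their mitochondrial fraction is
elevated, and they lack nuclear-retained transcripts. This module computes
those contamination-related metrics per droplet, clusters droplets in the
standardized metric space, removes clusters that look empty or
contaminated, and finally applies per-sample MAD-based outlier filtering of
the splicing and mitochondrial fractions. Doublet detection is an external
stage; a precomputed doublet mask can be passed through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression_pipeline import normalize_log1p, score_gene_set

__all__ = [
    "QCRules",
    "QCConfig",
    "QCFilterResult",
    "compute_qc_metrics",
    "cluster_quality_space",
    "flag_contaminated_clusters",
    "sample_outlier_filter",
    "run_droplet_qc",
]

REQUIRED_SETS = ("mito", "nuclear", "cardiomyocyte")


@dataclass
class QCRules:
    """Cluster-level removal thresholds.

    A cluster is proposed contaminated when its mean mitochondrial fraction
    exceeds ``mito_max``, and empty when its mean splicing fraction exceeds
    ``splicing_max`` while its mean nuclear score falls below the
    ``nuclear_quantile`` quantile of all cluster-mean nuclear scores.
    """

    splicing_max: float = 0.7
    mito_max: float = 0.3
    nuclear_quantile: float = 0.5

    def validate(self) -> None:
        for name in ("splicing_max", "mito_max", "nuclear_quantile"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QCConfig:
    k: int = 4
    rules: QCRules = field(default_factory=QCRules)
    n_mads: float = 4.0
    score_n_bins: int = 25
    score_n_ctrl: int = 50
    seed: int = 0


@dataclass
class QCFilterResult:
    keep_mask: np.ndarray
    cluster_label: np.ndarray
    removal_reason: np.ndarray  # kept|empty_cluster|contaminated_cluster|sample_outlier|doublet
    per_sample_summary: dict
    metrics: pd.DataFrame


def compute_qc_metrics(
    counts: ad.AnnData,
    gene_sets: Mapping[str, Sequence[str]],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-droplet contamination/quality metrics.

    Requires ``spliced``/``unspliced`` layers and gene sets named ``mito``,
    ``nuclear``, ``cardiomyocyte`` plus at least one further (non-CM
    marker) set. Fractions come from raw counts; enrichment scores use the
    binned control-gene scorer on the log-normalized matrix. Row order
    matches the barcode order of the input.
    """
    if "spliced" not in counts.layers or "unspliced" not in counts.layers:
        raise ValueError("counts must carry spliced/unspliced layers")
    missing_sets = [s for s in REQUIRED_SETS if s not in gene_sets]
    if missing_sets:
        raise ValueError(f"missing required gene sets: {missing_sets}")
    noncm_names = [
        s for s in gene_sets if s not in ("mito", "nuclear", "cardiomyocyte")
    ]
    if not noncm_names:
        raise ValueError("at least one non-cardiomyocyte marker set is required")

    x = np.asarray(counts.X, dtype=float)
    spliced = np.asarray(counts.layers["spliced"], dtype=float)
    total = x.sum(axis=1)
    spliced_total = spliced.sum(axis=1)
    zero = total == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} droplets have zero counts; "
                      "splicing fraction set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        splicing_fraction = np.where(zero, 0.0, spliced_total / np.maximum(total, 1))

    mito_genes = [g for g in gene_sets["mito"] if g in counts.var_names]
    _warn_dropped("mito", gene_sets["mito"], mito_genes)
    if not mito_genes:
        raise ValueError("mito gene set empty after intersection")
    mito_ix = counts.var_names.get_indexer(mito_genes)
    mito_fraction = np.where(zero, 0.0, x[:, mito_ix].sum(axis=1) / np.maximum(total, 1))

    # enrichment scores on log-normalized data (zero-count droplets are
    # dropped by normalization, so score them as 0)
    keep = ~zero
    norm = normalize_log1p(counts[keep].copy()) if keep.any() else None

    def scored(name: str, members: Sequence[str], offset: int) -> np.ndarray:
        present = [g for g in members if g in counts.var_names]
        _warn_dropped(name, members, present)
        if not present:
            raise ValueError(f"gene set {name!r} empty after intersection")
        out = np.zeros(counts.n_obs)
        if norm is not None:
            out[keep] = score_gene_set(
                norm, present, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + offset
            )
        return out

    metrics = pd.DataFrame(index=counts.obs_names)
    metrics["total_counts"] = total
    metrics["n_genes"] = (x > 0).sum(axis=1)
    metrics["splicing_fraction"] = splicing_fraction
    metrics["mito_fraction"] = mito_fraction
    metrics["nuclear_score"] = scored("nuclear", gene_sets["nuclear"], 1)
    metrics["cm_score"] = scored("cardiomyocyte", gene_sets["cardiomyocyte"], 2)
    for j, name in enumerate(noncm_names):
        metrics[f"score_{name}"] = scored(name, gene_sets[name], 3 + j)
    metrics["max_noncm_score"] = metrics[
        [f"score_{n}" for n in noncm_names]
    ].max(axis=1)
    return metrics


def _warn_dropped(name: str, requested: Sequence[str], present: Sequence[str]) -> None:
    n_missing = len(list(requested)) - len(present)
    if n_missing:
        warnings.warn(f"{n_missing} members of gene set {name!r} absent from "
                      "the feature list; dropped", stacklevel=3)


_CLUSTER_COLUMNS = [
    "total_counts", "n_genes", "splicing_fraction", "mito_fraction",
    "nuclear_score", "cm_score", "max_noncm_score",
]


def cluster_quality_space(
    metrics: pd.DataFrame, k: int = 4, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """k-means partition of droplets in the standardized quality space."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(metrics) < k:
        raise ValueError(f"fewer droplets ({len(metrics)}) than clusters ({k})")
    cols = [c for c in _CLUSTER_COLUMNS if c in metrics.columns]
    x = metrics[cols].to_numpy(float)
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.all():
        raise ValueError("degenerate input: all quality metrics constant")
    if degenerate.any():
        warnings.warn(
            f"dropping zero-variance metric columns: "
            f"{[c for c, d in zip(cols, degenerate) if d]}", stacklevel=2)
    x = (x[:, ~degenerate] - x[:, ~degenerate].mean(axis=0)) / sd[~degenerate]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(x).astype(np.int64)


def flag_contaminated_clusters(
    labels: np.ndarray, metrics: pd.DataFrame, rules: QCRules | None = None
) -> np.ndarray:
    """Cluster-level removal proposal.

    Clusters are judged on their mean metrics: mitochondrial overload marks
    a contaminated cluster; a high spliced fraction combined with a
    below-quantile nuclear score marks an empty cluster (the mitochondrial
    rule takes precedence when both fire). Returns one of
    ``kept|empty_cluster|contaminated_cluster`` per droplet.
    """
    rules = rules or QCRules()
    rules.validate()
    labels = np.asarray(labels)
    means = metrics.groupby(labels).mean(numeric_only=True)
    nuclear_thresh = means["nuclear_score"].quantile(rules.nuclear_quantile)
    reason = np.full(len(labels), "kept", dtype=object)
    for cluster, row in means.iterrows():
        if row["mito_fraction"] > rules.mito_max:
            reason[labels == cluster] = "contaminated_cluster"
        elif (
            row["splicing_fraction"] > rules.splicing_max
            and row["nuclear_score"] < nuclear_thresh
        ):
            reason[labels == cluster] = "empty_cluster"
    return reason


def sample_outlier_filter(
    metrics: pd.DataFrame,
    sample_ids: np.ndarray,
    keep_mask: np.ndarray,
    n_mads: float = 4.0,
) -> np.ndarray:
    """Per-sample one-sided MAD filter on splicing and mito fractions.

    Within each sample, among currently kept droplets, droplets strictly
    above median + n_mads * 1.4826 * MAD of either fraction are dropped
    (high side only). Samples with fewer than 3 kept droplets are skipped.
    With MAD = 0 the threshold collapses to the median, so only strictly
    greater values are dropped.
    """
    sample_ids = np.asarray(sample_ids)
    keep = np.asarray(keep_mask, bool).copy()
    for sample in np.unique(sample_ids):
        in_s = (sample_ids == sample) & keep
        if in_s.sum() < 3:
            warnings.warn(f"sample {sample!r} has <3 kept droplets; skipped",
                          stacklevel=2)
            continue
        for col in ("splicing_fraction", "mito_fraction"):
            v = metrics.loc[in_s, col].to_numpy(float)
            med = np.median(v)
            mad = 1.4826 * np.median(np.abs(v - med))
            thresh = med + n_mads * mad
            if np.isinf(thresh) or np.isnan(thresh):
                continue
            over = np.zeros(len(keep), bool)
            over[np.flatnonzero(in_s)[v > thresh]] = True
            keep &= ~over
    return keep


def run_droplet_qc(
    counts: ad.AnnData,
    gene_sets: Mapping[str, Sequence[str]],
    config: QCConfig | None = None,
    doublet_mask: np.ndarray | None = None,
) -> QCFilterResult:
    """Full droplet-filtering chain: metrics -> quality-space clustering ->
    cluster removal -> per-sample MAD filtering -> optional doublet mask."""
    if counts.n_obs == 0:
        raise ValueError("empty count matrix")
    cfg = config or QCConfig()
    metrics = compute_qc_metrics(
        counts, gene_sets, cfg.score_n_bins, cfg.score_n_ctrl, cfg.seed
    )
    labels = cluster_quality_space(metrics, cfg.k, cfg.seed)
    reason = flag_contaminated_clusters(labels, metrics, cfg.rules)
    keep = reason == "kept"

    samples = (
        counts.obs["sample"].to_numpy()
        if "sample" in counts.obs
        else np.full(counts.n_obs, "all")
    )
    kept_after = sample_outlier_filter(metrics, samples, keep, cfg.n_mads)
    reason[keep & ~kept_after] = "sample_outlier"
    keep = kept_after

    if doublet_mask is not None:
        doublet_mask = np.asarray(doublet_mask, bool)
        reason[keep & doublet_mask] = "doublet"
        keep = keep & ~doublet_mask

    retained = pd.Series(samples)[keep].value_counts().sort_index()
    summary = {
        "retained_per_sample": {str(k): int(v) for k, v in retained.items()},
        "median": float(retained.median()) if len(retained) else 0.0,
        "mean": float(retained.mean()) if len(retained) else 0.0,
    }
    return QCFilterResult(
        keep_mask=keep,
        cluster_label=labels,
        removal_reason=reason,
        per_sample_summary=summary,
        metrics=metrics,
    )
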