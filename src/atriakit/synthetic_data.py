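"""Synthetic data generators with planted ground truth.

Every downstream stage of the toolkit (droplet QC, co-expression module
detection, hexagonal spatial binning, DE-table comparison statistics) is
exercised on data from this module, so each generator plants a known truth:

* :func:`generate_droplet_dataset` emulates a single-nuclei RNA-seq droplet
  population containing true nuclei of several cell types, empty droplets
  dominated by cytoplasmic ambient RNA (high spliced fraction, high
  mitochondrial fraction, low nuclear-gene content), and contaminated
  nuclei in between.
* :func:`generate_module_dataset` plants correlated gene modules through a
  single-factor model per module; two genes in a module with factor loading
  ``l`` have population correlation ``l**2``.
* :func:`generate_molecule_table` lays out spatially segregated expression
  domains on a slide and scatters transcript molecules inside them.
* :func:`generate_de_comparison` constructs two differential-expression
  tables with a requested significant-set overlap and logFC correlation.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "DropletSimConfig",
    "ModuleSimConfig",
    "GroundTruth",
    "generate_droplet_dataset",
    "generate_module_dataset",
    "generate_molecule_table",
    "generate_de_comparison",
    "droplet_gene_sets",
]


# ---------------------------------------------------------------------------
# configuration and ground-truth containers
# ---------------------------------------------------------------------------

#: default per-class Beta(alpha, beta) parameters of the per-droplet spliced
#: fraction. Nuclei are dominated by unspliced pre-mRNA (mean ~0.35); ambient
#: RNA in empty droplets is cytoplasmic and almost fully spliced (mean ~0.95);
#: contaminated nuclei sit in between (mean ~0.75).
DEFAULT_SPLICED_PARAMS: dict[str, tuple[float, float]] = {
    "nucleus": (7.0, 13.0),
    "empty": (38.0, 2.0),
    "contaminated": (15.0, 5.0),
}

#: default per-class negative-binomial (mean, dispersion) of droplet depth.
DEFAULT_DEPTH_PARAMS: dict[str, tuple[float, float]] = {
    "nucleus": (3000.0, 8.0),
    "empty": (800.0, 4.0),
    "contaminated": (2500.0, 6.0),
}

#: per-class weight of the mitochondrial and nuclear-enriched gene blocks in
#: the expression profile. Empty/contaminated droplets carry more
#: mitochondrial ambient RNA and less nuclear-retained transcript.
DEFAULT_BLOCK_WEIGHTS: dict[str, tuple[float, float]] = {
    # class -> (mito weight, nuclear weight)
    "nucleus": (0.02, 0.30),
    "empty": (0.15, 0.02),
    "contaminated": (0.40, 0.08),
}


def _default_class_fractions() -> dict[str, float]:
    # 30% empty and 10% contaminated droplets, the remainder nuclei of three
    # cardiac cell types (cardiomyocytes dominate right-atrial tissue).
    return {
        "nucleus_CM": 0.30,
        "nucleus_FB": 0.18,
        "nucleus_EC": 0.12,
        "empty": 0.30,
        "contaminated": 0.10,
    }


@dataclass
class DropletSimConfig:
    """Configuration of the droplet-population simulator."""

    n_droplets: int = 2000
    class_fractions: dict[str, float] = field(default_factory=_default_class_fractions)
    n_genes: int = 1200
    n_mito_genes: int = 13
    n_nuclear_genes: int = 50
    markers_per_type: int = 30
    spliced_fraction_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SPLICED_PARAMS)
    )
    depth_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_PARAMS)
    )
    #: mixing weights of the cell-type profiles inside the ambient profile;
    #: None means proportional to the nucleus-class fractions.
    ambient_profile_weights: dict[str, float] | None = None
    n_samples: int = 4
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        for name, frac in self.class_fractions.items():
            if frac < 0 or frac > 1:
                raise ValueError(f"class fraction {name}={frac} outside [0,1]")
            if not (name.startswith("nucleus_") or name in ("empty", "contaminated")):
                raise ValueError(f"unknown droplet class {name!r}")
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        for cls, (a, b) in self.spliced_fraction_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {cls} must be positive")
        for cls, (mu, disp) in self.depth_params.items():
            if mu <= 0 or disp <= 0:
                raise ValueError(f"depth parameters for {cls} must be positive")
        n_marker = self.markers_per_type * len(self.celltypes)
        reserved = self.n_mito_genes + self.n_nuclear_genes + n_marker
        if reserved > self.n_genes:
            raise ValueError(
                f"gene blocks ({reserved}) exceed n_genes ({self.n_genes})"
            )

    @property
    def celltypes(self) -> list[str]:
        return sorted(
            c.removeprefix("nucleus_")
            for c in self.class_fractions
            if c.startswith("nucleus_")
        )


@dataclass
class ModuleSimConfig:
    """Configuration of the planted-module expression simulator."""

    n_cells: int = 5000
    n_genes: int = 200
    module_sizes: Sequence[int] = (20, 20, 20, 20)
    loading: float | Sequence[float] = 0.8
    mode: str = "gaussian"  # or "counts"
    sparsity_target: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")
        loadings = self.loadings
        if any(not (0.0 <= l < 1.0) for l in loadings):
            raise ValueError("loadings must lie in [0, 1)")
        if self.mode not in ("gaussian", "counts"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.sparsity_target < 1.0):
            raise ValueError("sparsity_target must lie in [0, 1)")

    @property
    def loadings(self) -> list[float]:
        if np.isscalar(self.loading):
            return [float(self.loading)] * len(self.module_sizes)
        return [float(l) for l in self.loading]


@dataclass
class GroundTruth:
    """Planted truth labels accompanying a generated object."""

    droplet_class: np.ndarray | None = None
    module_of_gene: np.ndarray | None = None
    domain_of_molecule: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {}
        for key in ("droplet_class", "module_of_gene", "domain_of_molecule"):
            val = getattr(self, key)
            if val is not None:
                out[key] = [x.item() if hasattr(x, "item") else x for x in val]
        return out


# ---------------------------------------------------------------------------
# droplet populations
# ---------------------------------------------------------------------------

def _class_key(cls: str) -> str:
    return "nucleus" if cls.startswith("nucleus_") else cls


def _lookup(params: Mapping[str, tuple[float, float]], cls: str) -> tuple[float, float]:
    """Per-class parameter lookup with fallback to the class family."""
    if cls in params:
        return params[cls]
    return params[_class_key(cls)]


def _build_profiles(cfg: DropletSimConfig, rng: np.random.Generator):
    """Per-class gene expression profiles (rows sum to 1).

    The gene axis is laid out as [mito | nuclear | markers per type |
    background]. Each cell type shares a common background, boosts its own
    marker block, and receives the class-family mito/nuclear block weights.
    The ambient profile is the abundance-weighted mixture of the cell-type
    profiles re-weighted toward cytoplasmic content (empty-class mito weight,
    nuclear block suppressed).
    """
    types = cfg.celltypes
    g = cfg.n_genes
    n_mito, n_nuc, n_mark = cfg.n_mito_genes, cfg.n_nuclear_genes, cfg.markers_per_type
    mito_ix = np.arange(n_mito)
    nuc_ix = np.arange(n_mito, n_mito + n_nuc)
    marker_ix = {
        t: np.arange(n_mito + n_nuc + i * n_mark, n_mito + n_nuc + (i + 1) * n_mark)
        for i, t in enumerate(types)
    }
    bg_start = n_mito + n_nuc + len(types) * n_mark
    bg_ix = np.arange(bg_start, g)

    base = rng.gamma(1.0, 1.0, size=g) + 0.05  # shared broken-stick background

    def assemble(mito_w: float, nuc_w: float, marker_type: str | None) -> np.ndarray:
        p = base.copy()
        # zero the structured blocks, then re-inject them at the class weight
        p[mito_ix] = 0.0
        p[nuc_ix] = 0.0
        for t in types:
            p[marker_ix[t]] *= 0.05  # weak off-type marker leakage
        if marker_type is not None:
            p[marker_ix[marker_type]] = base[marker_ix[marker_type]] * 12.0
        p /= p.sum()
        rest = 1.0 - mito_w - nuc_w
        p *= rest
        p[mito_ix] = mito_w * (base[mito_ix] / base[mito_ix].sum())
        p[nuc_ix] = nuc_w * (base[nuc_ix] / base[nuc_ix].sum())
        return p

    mito_w, nuc_w = DEFAULT_BLOCK_WEIGHTS["nucleus"]
    type_profiles = {t: assemble(mito_w, nuc_w, t) for t in types}

    if cfg.ambient_profile_weights is None:
        w = np.array([cfg.class_fractions[f"nucleus_{t}"] for t in types], float)
    else:
        w = np.array([cfg.ambient_profile_weights[t] for t in types], float)
    w = w / w.sum() if w.sum() > 0 else np.full(len(types), 1.0 / len(types))
    ambient_mix = sum(wi * type_profiles[t] for wi, t in zip(w, types))

    def reweight(profile: np.ndarray, mito_w: float, nuc_w: float) -> np.ndarray:
        p = profile.copy()
        body = 1.0 - p[mito_ix].sum() - p[nuc_ix].sum()
        p[mito_ix] *= mito_w / max(p[mito_ix].sum(), 1e-300)
        p[nuc_ix] *= nuc_w / max(p[nuc_ix].sum(), 1e-300)
        scale = (1.0 - mito_w - nuc_w) / body
        mask = np.ones(g, bool)
        mask[mito_ix] = False
        mask[nuc_ix] = False
        p[mask] *= scale
        return p / p.sum()

    profiles = {f"nucleus_{t}": p for t, p in type_profiles.items()}
    e_mito, e_nuc = DEFAULT_BLOCK_WEIGHTS["empty"]
    profiles["empty"] = reweight(ambient_mix, e_mito, e_nuc)
    c_mito, c_nuc = DEFAULT_BLOCK_WEIGHTS["contaminated"]
    # contaminated nuclei: a nucleus profile mixed 50/50 with ambient, with
    # elevated mitochondrial load
    contam_base = 0.5 * ambient_mix + 0.5 * sum(type_profiles.values()) / len(types)
    profiles["contaminated"] = reweight(contam_base, c_mito, c_nuc)

    categories = np.array(
        ["mito"] * n_mito
        + ["nuclear"] * n_nuc
        + sum(([f"marker_{t}"] * n_mark for t in types), [])
        + ["background"] * len(bg_ix)
    )
    return profiles, categories


def generate_droplet_dataset(cfg: DropletSimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a droplet count matrix with a spliced/unspliced split.

    Returns an :class:`anndata.AnnData` whose ``X`` holds total counts and
    whose ``spliced``/``unspliced`` layers partition it exactly, plus the
    planted per-droplet class labels.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    profiles, categories = _build_profiles(cfg, rng)

    classes = sorted(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in classes])
    labels = rng.choice(classes, size=cfg.n_droplets, p=probs)

    total = np.zeros((cfg.n_droplets, cfg.n_genes), dtype=np.int64)
    spliced = np.zeros_like(total)
    for i, cls in enumerate(labels):
        mu, disp = _lookup(cfg.depth_params, cls)
        # NB(mean mu, dispersion r) as gamma-mixed Poisson
        lam = rng.gamma(disp, mu / disp)
        depth = max(int(rng.poisson(lam)), 1)
        counts = rng.multinomial(depth, profiles[cls])
        a, b = _lookup(cfg.spliced_fraction_params, cls)
        frac = rng.beta(a, b)
        total[i] = counts
        spliced[i] = rng.binomial(counts, frac)

    gene_names = [f"MT-{j}" for j in range(cfg.n_mito_genes)] + [
        f"G{j:05d}" for j in range(cfg.n_mito_genes, cfg.n_genes)
    ]
    barcodes = [f"BC{i:06d}" for i in range(cfg.n_droplets)]
    samples = np.array(
        [f"S{(i % cfg.n_samples) + 1}" for i in range(cfg.n_droplets)]
    )
    adata = ad.AnnData(
        X=total.astype(np.float64),
        obs=pd.DataFrame({"sample": samples, "droplet_class": labels}, index=barcodes),
        var=pd.DataFrame({"category": categories}, index=gene_names),
        layers={
            "spliced": spliced.astype(np.float64),
            "unspliced": (total - spliced).astype(np.float64),
        },
    )
    return adata, GroundTruth(droplet_class=labels)


def droplet_gene_sets(adata: ad.AnnData) -> dict[str, list[str]]:
    """Gene-set collection (mito / nuclear / per-type markers) implied by the
    ``category`` annotation of a simulated droplet dataset."""
    cat = adata.var["category"]
    sets: dict[str, list[str]] = {
        "mito": list(adata.var_names[cat == "mito"]),
        "nuclear": list(adata.var_names[cat == "nuclear"]),
    }
    for c in sorted(cat.unique()):
        if c.startswith("marker_"):
            t = c.removeprefix("marker_")
            name = "cardiomyocyte" if t == "CM" else t
            sets[name] = list(adata.var_names[cat == c])
    return sets


# ---------------------------------------------------------------------------
# planted co-expression modules
# ---------------------------------------------------------------------------

def generate_module_dataset(cfg: ModuleSimConfig) -> tuple[np.ndarray, GroundTruth]:
    """Expression matrix with planted correlated gene modules.

    Single-factor model: module ``m`` has one standard-normal factor per
    cell; a member gene with loading ``l`` equals ``l*f + sqrt(1-l^2)*eps``,
    so two member genes correlate at ``l**2``. Background genes are pure
    noise. In ``counts`` mode the latent values are exponentiated, Poisson
    sampled, and Bernoulli-thinned so the expected zero fraction matches
    ``sparsity_target`` (in expectation, not exactly).

    Returns the cells x genes matrix and per-gene module ids (-1 for
    background genes).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_cells, cfg.n_genes
    membership = np.full(g, -1, dtype=np.int64)
    latent = rng.standard_normal((n, g))
    start = 0
    for m, (size, l) in enumerate(zip(cfg.module_sizes, cfg.loadings)):
        ix = np.arange(start, start + size)
        membership[ix] = m
        f = rng.standard_normal(n)
        latent[:, ix] = l * f[:, None] + np.sqrt(1.0 - l * l) * latent[:, ix]
        start += size

    if cfg.mode == "gaussian":
        return latent, GroundTruth(module_of_gene=membership)

    rates = np.exp(latent)
    if cfg.sparsity_target > 0.0:
        keep = _thinning_probability(rates, cfg.sparsity_target)
    else:
        keep = 1.0
    counts = rng.poisson(keep * rates).astype(np.float64)
    return counts, GroundTruth(module_of_gene=membership)


def _thinning_probability(rates: np.ndarray, target_zero_fraction: float) -> float:
    """Bernoulli keep-probability giving the requested expected zero fraction.

    Thinning Poisson(rate) by keep-probability p yields Poisson(p*rate), so
    the expected zero fraction is mean(exp(-p*rate)); solve for p.
    """
    flat = rates.ravel()

    def zero_frac(p: float) -> float:
        return float(np.mean(np.exp(-p * flat)))

    if zero_frac(1.0) >= target_zero_fraction:
        warnings.warn(
            "data already sparser than sparsity_target; no thinning applied",
            stacklevel=2,
        )
        return 1.0
    return float(brentq(lambda p: zero_frac(p) - target_zero_fraction, 1e-12, 1.0))


# ---------------------------------------------------------------------------
# spatial molecule tables
# ---------------------------------------------------------------------------

def generate_molecule_table(
    width: float,
    height: float,
    domains: Sequence[tuple],
    n_molecules: int,
    seed: int = 0,
    section: str = "section1",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Scatter transcript molecules inside spatial expression domains.

    Parameters
    ----------
    width, height
        Slide dimensions in pixels; the slide rectangle is
        ``[0, width] x [0, height]``.
    domains
        List of ``(shape, gene_profile)`` pairs. ``shape`` is either
        ``("disc", cx, cy, r)`` or ``("rect", x0, y0, x1, y1)`` and must lie
        inside the slide; ``gene_profile`` maps gene symbol to sampling
        weight.
    n_molecules
        Total number of molecules, split evenly across domains (remainder to
        the first domains).

    Returns the molecule table (x, y, gene, section) and the per-molecule
    domain label.
    """
    if not domains:
        raise ValueError("at least one domain is required")
    for shape, _profile in domains:
        _check_domain_inside(shape, width, height)
    rng = np.random.default_rng(seed)
    per_domain = np.full(len(domains), n_molecules // len(domains))
    per_domain[: n_molecules % len(domains)] += 1

    xs, ys, genes, doms = [], [], [], []
    for d, ((shape, profile), count) in enumerate(zip(domains, per_domain)):
        if count == 0:
            continue
        px, py = _sample_in_shape(shape, count, rng)
        names = list(profile)
        w = np.array([profile[g] for g in names], float)
        w /= w.sum()
        gs = rng.choice(names, size=count, p=w)
        xs.append(px)
        ys.append(py)
        genes.append(gs)
        doms.append(np.full(count, d))

    if xs:
        table = pd.DataFrame(
            {
                "x": np.concatenate(xs),
                "y": np.concatenate(ys),
                "gene": np.concatenate(genes),
                "section": section,
            }
        )
        domain_of_molecule = np.concatenate(doms)
    else:
        table = pd.DataFrame(
            {"x": pd.Series(dtype=float), "y": pd.Series(dtype=float),
             "gene": pd.Series(dtype=object), "section": pd.Series(dtype=object)}
        )
        domain_of_molecule = np.array([], dtype=np.int64)
    return table, GroundTruth(domain_of_molecule=domain_of_molecule)


def _check_domain_inside(shape: tuple, width: float, height: float) -> None:
    kind = shape[0]
    if kind == "disc":
        _, cx, cy, r = shape
        if cx - r < 0 or cy - r < 0 or cx + r > width or cy + r > height:
            raise ValueError(f"disc {shape} extends outside the slide")
    elif kind == "rect":
        _, x0, y0, x1, y1 = shape
        if x0 < 0 or y0 < 0 or x1 > width or y1 > height or x0 >= x1 or y0 >= y1:
            raise ValueError(f"rect {shape} invalid or outside the slide")
    else:
        raise ValueError(f"unknown domain shape {kind!r}")


def _sample_in_shape(shape: tuple, n: int, rng: np.random.Generator):
    kind = shape[0]
    if kind == "disc":
        _, cx, cy, r = shape
        theta = rng.uniform(0, 2 * np.pi, n)
        rad = r * np.sqrt(rng.uniform(0, 1, n))
        return cx + rad * np.cos(theta), cy + rad * np.sin(theta)
    _, x0, y0, x1, y1 = shape
    return rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)


# ---------------------------------------------------------------------------
# paired DE tables
# ---------------------------------------------------------------------------

def generate_de_comparison(
    n_genes: int,
    shared_fraction: float,
    logfc_correlation: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Two DE result tables with controlled significant-set overlap.

    Half the gene universe is significant in at least one table; of that
    union, ``shared_fraction`` is significant in both (so the expected
    Jaccard index equals ``shared_fraction`` up to rounding). Shared genes
    draw their logFC pair from a bivariate normal with the requested
    correlation. Returns both tables and the constructed Jaccard value.
    """
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must lie in [0,1]")
    if not (-1.0 <= logfc_correlation <= 1.0):
        raise ValueError("logfc_correlation must lie in [-1,1]")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{j:05d}" for j in range(n_genes)])
    union = n_genes // 2
    n_shared = round(shared_fraction * union)
    only = union - n_shared
    n_a_only = only // 2
    n_b_only = only - n_a_only
    shared = genes[:n_shared]
    a_only = genes[n_shared : n_shared + n_a_only]
    b_only = genes[n_shared + n_a_only : union]
    expected_jaccard = n_shared / union if union else 0.0

    rho = logfc_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    pair = rng.multivariate_normal([0.0, 0.0], cov, size=n_shared)

    def build(sig_extra: np.ndarray, shared_fc: np.ndarray) -> pd.DataFrame:
        logfc = rng.normal(0.0, 0.2, n_genes)
        pval = rng.uniform(0.05, 1.0, n_genes)
        sig = np.zeros(n_genes, bool)
        lookup = {g: i for i, g in enumerate(genes)}
        for g, fc in zip(shared, shared_fc):
            i = lookup[g]
            sig[i] = True
            logfc[i] = fc
            pval[i] = rng.uniform(0.0, 1e-4)
        for g in sig_extra:
            i = lookup[g]
            sig[i] = True
            logfc[i] = rng.normal(0.0, 1.0)
            pval[i] = rng.uniform(0.0, 1e-4)
        m = n_genes
        order = np.argsort(pval)
        fdr = np.empty(m)
        fdr[order] = np.minimum.accumulate((pval[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        return pd.DataFrame(
            {"gene": genes, "logFC": logfc, "pvalue": pval,
             "fdr": np.minimum(fdr, 1.0), "significant": sig}
        )

    table_a = build(a_only, pair[:, 0])
    table_b = build(b_only, pair[:, 1])
    return table_a, table_b, float(expected_jaccard)
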