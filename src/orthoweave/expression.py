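"""Cell QC, normalization, variable-gene selection and PCA.

The preprocessing rules are written out explicitly rather than delegated to a
pipeline framework:

- QC keeps a cell iff it detects strictly more than ``min_genes`` genes and
  its mitochondrial count fraction is at most ``max_mito``.
- Normalization is the log-normalize transform
  ``ln(1 + count * scale_factor / cell_total)`` with scale factor 1e5.
- Variable genes are ranked by variance standardized against a 20-bin median
  mean-variance trend (a dependency-light stand-in for a loess trend fit).
- PCA runs on centered/unit-scaled (optionally per species) values clipped at
  +/-10, via an exact SVD, with a fixed sign convention.

Per-species centering and scaling is the package's stand-in for anchor-based
integration: it removes per-species location/scale shifts in gene space
before the species are embedded together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Cell-filtering thresholds.

    ``min_genes``: cells are kept strictly above this detected-gene count
    (the default removes cells expressing no more than 200 genes).
    ``max_mito``: maximum tolerated mitochondrial count fraction, inclusive.
    """

    min_genes: int = 200
    max_mito: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if not 0 <= self.max_mito <= 1:
            raise ValueError("max_mito must be in [0, 1]")


def mito_fraction(counts: AnnData, mito_prefix: str = "MT-") -> np.ndarray:
    """Per-cell fraction of counts on mitochondrial (prefix-named) genes."""
    is_mito = np.array([g.upper().startswith(mito_prefix.upper()) for g in counts.var_names])
    x = sp.csr_matrix(counts.X)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if not is_mito.any():
        warnings.warn(
            f"no genes with prefix {mito_prefix!r}; mitochondrial fraction treated as 0",
            stacklevel=2,
        )
        return np.zeros(counts.n_obs)
    mito = np.asarray(x[:, is_mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac


def qc_filter(counts: AnnData, cfg: QCConfig | None = None) -> tuple[AnnData, pd.DataFrame]:
    """Filter low-quality cells; returns the kept matrix and a QC report.

    A cell passes iff (detected genes > min_genes) and (mito fraction <= max_mito).
    The report counts removals per criterion (a cell failing both counts in both).
    """
    cfg = cfg or QCConfig()
    x = sp.csr_matrix(counts.X)
    n_detected = np.asarray((x > 0).sum(axis=1)).ravel()
    frac = mito_fraction(counts, cfg.mito_prefix)
    pass_genes = n_detected > cfg.min_genes
    pass_mito = frac <= cfg.max_mito
    keep = pass_genes & pass_mito
    report = pd.DataFrame(
        {
            "n_cells_in": [counts.n_obs],
            "n_cells_kept": [int(keep.sum())],
            "removed_low_genes": [int((~pass_genes).sum())],
            "removed_high_mito": [int((~pass_mito).sum())],
        }
    )
    logger.info(
        "qc_filter: kept %d/%d cells (%d low-gene, %d high-mito removals)",
        keep.sum(), counts.n_obs, (~pass_genes).sum(), (~pass_mito).sum(),
    )
    out = counts[keep].copy()
    out.obs["n_genes_detected"] = n_detected[keep]
    out.obs["mito_fraction"] = frac[keep]
    return out, report


def log_normalize(counts: AnnData, scale_factor: float = 100_000.0) -> AnnData:
    """Log-normalize: value = ln(1 + count * scale_factor / cell_total).

    All-zero cells map to all-zero columns. For every cell with nonzero total,
    sum over genes of expm1(value) equals ``scale_factor`` exactly (up to
    floating-point round-off).
    """
    x = sp.csr_matrix(counts.X).astype(np.float64)
    totals = np.asarray(x.sum(axis=1)).ravel()
    scale = np.where(totals > 0, scale_factor / np.maximum(totals, 1e-300), 0.0)
    x = sp.diags(scale) @ x
    x.data = np.log1p(x.data)
    out = AnnData(X=x.tocsr(), obs=counts.obs.copy(), var=counts.var.copy())
    out.uns["scale_factor"] = scale_factor
    out.uns["log_base"] = "e"
    return out


def _gene_mean_var(x: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).sum(axis=0)).ravel()
    var = (sq - n * mean**2) / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvg(norm: AnnData, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by trend-standardized variance.

    Genes are binned into ``n_bins`` equal-occupancy bins of log10(mean+eps);
    each gene's variance is divided by its bin's median variance and genes are
    ranked by that ratio. Ties break by gene symbol, so selection is fully
    deterministic.
    """
    mean, var = _gene_mean_var(sp.csr_matrix(norm.X))
    genes = np.array(norm.var_names)
    if n >= len(genes):
        if n > len(genes):
            warnings.warn(f"requested {n} HVGs but only {len(genes)} genes present", stacklevel=2)
        return sorted(genes.tolist())

    log_mean = np.log10(mean + 1e-12)
    order = np.argsort(log_mean, kind="mergesort")
    bins = np.empty(len(genes), dtype=int)
    bins[order] = np.minimum((np.arange(len(genes)) * n_bins) // len(genes), n_bins - 1)
    trend = np.ones(len(genes))
    for b in range(n_bins):
        in_bin = bins == b
        if in_bin.any():
            med = np.median(var[in_bin])
            trend[in_bin] = med if med > 0 else 1.0
    std_var = var / trend

    # rank by (-standardized variance, symbol): deterministic ties
    idx = sorted(range(len(genes)), key=lambda i: (-std_var[i], genes[i]))
    return sorted(genes[idx[:n]].tolist())


def scale_and_pca(
    norm: AnnData,
    hvg: list[str],
    n_pcs: int = 30,
    group_by_species: bool = True,
    clip: float = 10.0,
) -> AnnData:
    """Center/scale HVG expression (per species if requested), clip, and embed.

    Returns the input AnnData (copy) with ``obsm['X_pca']`` (cells x n_pcs),
    ``varm`` loadings for HVGs and ``uns['pca_variance_ratio']``. The sign of
    each component is fixed so its largest-magnitude gene loading is positive.
    """
    if n_pcs > len(hvg):
        raise ValueError(f"n_pcs={n_pcs} exceeds HVG count {len(hvg)}")
    if norm.n_obs < n_pcs:
        raise ValueError(f"fewer cells ({norm.n_obs}) than components ({n_pcs})")
    sub = norm[:, hvg]
    x = np.asarray(sp.csr_matrix(sub.X).todense(), dtype=np.float64)

    if group_by_species and "species" in norm.obs:
        groups = norm.obs["species"].to_numpy()
    else:
        groups = np.zeros(norm.n_obs, dtype=int)
    scaled = np.empty_like(x)
    for g in pd.unique(groups):
        mask = groups == g
        mu = x[mask].mean(axis=0)
        sd = x[mask].std(axis=0, ddof=1) if mask.sum() > 1 else np.ones(x.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        scaled[mask] = (x[mask] - mu) / sd
    np.clip(scaled, -clip, clip, out=scaled)

    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(scaled)
    load = pca.components_  # n_pcs x genes
    signs = np.sign(load[np.arange(n_pcs), np.argmax(np.abs(load), axis=1)])
    signs = np.where(signs == 0, 1.0, signs)
    scores = scores * signs
    load = load * signs[:, None]

    out = norm.copy()
    out.obsm["X_pca"] = scores
    out.uns["pca_variance_ratio"] = pca.explained_variance_ratio_
    out.uns["pca_hvg"] = list(hvg)
    out.uns["pca_loadings"] = load
    return out
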