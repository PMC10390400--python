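"""End-to-end orchestration of the harmonization + clustering pipeline.

Chains the stages in their canonical order: homology -> meta-gene table ->
per-species aggregation -> pooled matrix -> QC -> log-normalization -> HVG ->
(per-species scaled) PCA -> SNN graph -> community detection -> marker-panel
annotation -> composition table. Used by the CLI, the acceptance script and
the end-to-end tests; planted-truth evaluation stays outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .cluster import (
    DEFAULT_MARKER_PANEL,
    annotate_clusters,
    build_knn_graph,
    cell_type_ratios,
    cluster_graph,
)
from .expression import QCConfig, log_normalize, qc_filter, scale_and_pca, select_hvg
from .harmonize import aggregate_counts, concat_species
from .orthology import MetaGeneTable, build_metagene_table
from .simulate import SimulationConfig, SyntheticTruth, generate_counts, generate_homology

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    homology: pd.DataFrame
    metagenes: MetaGeneTable
    pooled: AnnData          # raw meta-gene counts, QC-passing cells
    qc_report: pd.DataFrame
    norm: AnnData            # log-normalized, with obsm['X_pca']
    hvg: list[str]
    labels: np.ndarray
    cells: pd.DataFrame      # barcode, species, cluster, cell_type
    ratios: pd.DataFrame
    truth: SyntheticTruth | None = None


def run_pooled_pipeline(
    pooled: AnnData,
    qc: QCConfig | None = None,
    scale_factor: float = 100_000.0,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    k: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    panel: dict[str, list[str]] | None = None,
) -> tuple[AnnData, pd.DataFrame, AnnData, list[str], np.ndarray, pd.DataFrame, pd.DataFrame]:
    """QC -> normalize -> HVG -> PCA -> cluster -> annotate on a pooled matrix."""
    kept, report = qc_filter(pooled, qc)
    norm = log_normalize(kept, scale_factor=scale_factor)
    hvg = select_hvg(norm, n=min(n_hvg, norm.n_vars))
    embedded = scale_and_pca(norm, hvg, n_pcs=min(n_pcs, len(hvg)), group_by_species=True)
    graph = build_knn_graph(embedded.obsm["X_pca"], k=k)
    labels = cluster_graph(graph, resolution=resolution, seed=seed)
    cells = annotate_clusters(embedded, labels, panel or DEFAULT_MARKER_PANEL)
    ratios = cell_type_ratios(cells)
    return kept, report, embedded, hvg, labels, cells, ratios


def run_synthetic_pipeline(
    config: SimulationConfig | None = None, **kwargs
) -> PipelineResult:
    """Generate synthetic data from ``config`` and run the full pipeline on it."""
    config = config or SimulationConfig()
    homology, truth_h = generate_homology(config)
    matrices, truth_c = generate_counts(config, homology)
    metagenes = build_metagene_table(homology, config.species_names)
    aggregated = [
        aggregate_counts(matrices[s], metagenes, s) for s in config.species_names
    ]
    pooled = concat_species(aggregated)
    kept, report, embedded, hvg, labels, cells, ratios = run_pooled_pipeline(
        pooled, seed=config.seed, **kwargs
    )
    truth = SyntheticTruth(
        cell_types=truth_c.cell_types,
        gene_programs=truth_c.gene_programs,
        metagene_of=truth_h.metagene_of,
        immune=truth_c.immune,
        planted_lr_pathway=truth_c.planted_lr_pathway,
    )
    return PipelineResult(
        homology=homology,
        metagenes=metagenes,
        pooled=kept,
        qc_report=report,
        norm=embedded,
        hvg=hvg,
        labels=labels,
        cells=cells,
        ratios=ratios,
        truth=truth,
    )


def truth_labels(truth: SyntheticTruth, adata: AnnData) -> pd.Series:
    """Planted cell-type labels aligned to an AnnData's (possibly QC-filtered)
    cells. For evaluation only — the pipeline never calls this."""
    lookup = {
        (s, f"C{i:05d}"): lab
        for s, labels in truth.cell_types.items()
        for i, lab in enumerate(labels)
    }
    keys = zip(adata.obs["species"], adata.obs["barcode"])
    return pd.Series([lookup[k] for k in keys], index=adata.obs_names)
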