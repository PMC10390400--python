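"""Neighbor-graph clustering, marker detection, annotation and composition.

Cells are embedded (PCA scores), joined into a shared-nearest-neighbor (SNN)
graph whose edges are Jaccard similarities of k-nearest-neighbor sets, and
partitioned by seeded modularity optimization. One-vs-rest Wilcoxon rank-sum
tests yield cluster markers; clusters are assigned a cell-type label by
scoring curated marker panels; per-species composition tables summarize the
annotation.
"""

from __future__ import annotations

import logging
import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.neighbors import NearestNeighbors

from ._stats import bh_adjust, rank_sum_test

logger = logging.getLogger(__name__)

#: Curated antral-epithelium marker panels (cell type -> meta-gene symbols).
#: GKN1/MUC5AC mark pit mucous cells, AQP5 the basal gland mucous cells,
#: PGC chief cells, ATP4A/ATP4B parietal cells, CHGA/CHGB endocrine cells,
#: HCK/DCLK1 tuft cells, MKI67/BIRC5/MCM6/PCNA proliferative cells and
#: F3/CLCA1/RRAD the pig-private F3+ cluster.
DEFAULT_MARKER_PANEL: dict[str, list[str]] = {
    "pit mucous cell": ["GKN1", "MUC5AC"],
    "proliferative cell": ["MKI67", "BIRC5", "MCM6", "PCNA"],
    "chief cell": ["PGC"],
    "tuft cell": ["HCK", "DCLK1"],
    "endocrine cell": ["CHGA", "CHGB"],
    "parietal cell": ["ATP4A", "ATP4B"],
    "BGMC": ["AQP5"],
    "F3+ cell": ["F3", "CLCA1", "RRAD"],
}

UNASSIGNED = "unassigned"


def build_knn_graph(embedding: np.ndarray, k: int = 20, prune: float = 1 / 15) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighbor set is itself plus its ``k`` nearest cells (Euclidean
    distance in the embedding). For every ordered kNN pair the edge
    weight is the Jaccard similarity of the two neighbor sets; the graph is
    undirected, weights symmetrized, self-edges excluded. Edges with Jaccard
    weight below ``prune`` (default 1/15, the convention of the neighbor-graph
    routine this reimplements) are dropped, which removes spurious weak links
    between unrelated neighborhoods.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neighbor_sets = [set(row) | {i} for i, row in enumerate(idx)]  # self included

    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in neighbor_sets[i]:
            if j == i:
                continue
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neighbor_sets[a] & neighbor_sets[b])
            union = len(neighbor_sets[a] | neighbor_sets[b])
            w = inter / union if union else 0.0
            if w >= prune and w > 0:
                edges.append((a, b))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges, edge_attrs={"weight": weights}, directed=False)
    return g


def cluster_graph(graph: ig.Graph, resolution: float = 0.8, seed: int = 0) -> np.ndarray:
    """Seeded modularity-based community detection on the SNN graph.

    Clusters are relabeled canonically: decreasing size, ties broken by the
    smallest member index, so the same partition always yields the same ids.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.array(part.membership)
    return relabel_by_size(raw)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids as dense integers by decreasing size (ties: smallest member)."""
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    keyed = sorted(uniq, key=lambda c: (-int((labels == c).sum()), int(np.argmax(labels == c))))
    mapping = {c: i for i, c in enumerate(keyed)}
    return np.array([mapping[c] for c in labels])


def _group_stats(x: sp.csr_matrix, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mean of expm1(values), detection fraction) per gene over masked cells."""
    sub = x[mask]
    expm1_mean = np.asarray(sub.expm1().mean(axis=0)).ravel() if sub.shape[0] else np.zeros(x.shape[1])
    pct = np.asarray((sub > 0).mean(axis=0)).ravel() if sub.shape[0] else np.zeros(x.shape[1])
    return expm1_mean, pct


def rank_sum_de(
    norm: AnnData,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    min_pct: float = 0.1,
    min_log2fc: float = 0.25,
) -> pd.DataFrame:
    """Shared rank-sum differential-expression machinery (group a vs group b).

    log2FC = log2((mean(expm1 x_a)+1) / (mean(expm1 x_b)+1)); genes pass the
    pre-filter when detected in at least ``min_pct`` of either group and
    |log2FC| >= ``min_log2fc``. P-values are two-sided Wilcoxon rank-sum.
    BH adjustment corrects over the full gene universe of the matrix
    (untested genes enter at p = 1), the convention of correcting across all
    features; adjusting only the pre-filter survivors would be
    anti-conservative, since large observed fold changes correlate with small
    rank-sum p-values under the null.
    """
    x = sp.csr_matrix(norm.X)
    mean_a, pct_a = _group_stats(x, mask_a)
    mean_b, pct_b = _group_stats(x, mask_b)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    tested = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(log2fc) >= min_log2fc)

    result = pd.DataFrame(
        {
            "gene": norm.var_names,
            "log2fc": log2fc,
            "pct_in": pct_a,
            "pct_out": pct_b,
        }
    )
    result["p"] = np.nan
    result["p_adj"] = np.nan
    if tested.any():
        xa = np.asarray(x[mask_a][:, tested].todense())
        xb = np.asarray(x[mask_b][:, tested].todense())
        _, p = rank_sum_test(xa, xb)
        result.loc[tested, "p"] = p
        full_p = np.ones(norm.n_vars)
        full_p[np.flatnonzero(tested)] = p
        result.loc[tested, "p_adj"] = bh_adjust(full_p)[np.flatnonzero(tested)]
    return result[tested].reset_index(drop=True), result


def find_markers(
    norm: AnnData,
    labels: np.ndarray | pd.Series,
    min_pct: float = 0.1,
    min_log2fc: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest marker detection for every cluster.

    Returns a table (gene, cluster, log2fc, pct_in, pct_out, p, p_adj) of
    pre-filter-passing genes, sorted within cluster by ascending p then
    descending log2FC. Clusters with a single cell are skipped with a warning.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters for one-vs-rest testing")
    frames = []
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < 2:
            warnings.warn(f"cluster {cl!r} has a single cell; skipped", stacklevel=2)
            continue
        tested, _ = rank_sum_de(norm, mask, ~mask, min_pct=min_pct, min_log2fc=min_log2fc)
        tested.insert(1, "cluster", cl)
        tested = tested.sort_values(["p", "log2fc"], ascending=[True, False])
        frames.append(tested)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene", "cluster", "log2fc", "pct_in", "pct_out", "p", "p_adj"]
    )


def annotate_clusters(
    norm: AnnData,
    labels: np.ndarray | pd.Series,
    panel: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Assign each cluster the best-scoring marker-panel cell type.

    Panel-gene expression is z-scored across all cells; a cluster's score for
    a type is the mean z over its cells and the type's present panel genes.
    The argmax type wins (ties broken by panel order); clusters whose best
    score is negative stay ``unassigned``.

    Returns a per-cell table: barcode, species, cluster, cell_type.
    """
    panel = panel or DEFAULT_MARKER_PANEL
    if not panel:
        raise ValueError("marker panel is empty")
    labels = np.asarray(labels)
    genes = {g.upper(): i for i, g in enumerate(norm.var_names)}
    present = {
        t: [genes[g.upper()] for g in gl if g.upper() in genes] for t, gl in panel.items()
    }
    missing = {t: [g for g in gl if g.upper() not in genes] for t, gl in panel.items()}
    for t, gl in missing.items():
        if gl:
            warnings.warn(f"panel {t!r}: symbols {gl} not in matrix", stacklevel=2)
    if not any(present.values()):
        raise ValueError("no panel gene present in the matrix")

    used = sorted({i for idxs in present.values() for i in idxs})
    x = np.asarray(sp.csr_matrix(norm.X)[:, used].todense())
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    z = (x - mu) / np.where(sd > 0, sd, 1.0)
    col_of = {gi: j for j, gi in enumerate(used)}
    # zero-variance panel genes carry no information; a type whose scorable
    # genes are all flat cannot win, and a cluster with no informative panel
    # signal stays unassigned
    scorable = {gi for gi in used if sd[col_of[gi]] > 0}
    usable = {t: [i for i in idxs if i in scorable] for t, idxs in present.items()}

    type_names = [t for t in panel if present[t]]
    assign: dict[int | str, str] = {}
    for cl in pd.unique(labels):
        mask = labels == cl
        scores = [
            z[np.ix_(mask, [col_of[i] for i in usable[t]])].mean() if usable[t] else -np.inf
            for t in type_names
        ]
        best = int(np.argmax(scores))  # argmax takes first max: panel-order tie-break
        assign[cl] = type_names[best] if scores[best] >= 0 else UNASSIGNED

    cells = pd.DataFrame(
        {
            "barcode": norm.obs["barcode"] if "barcode" in norm.obs else norm.obs_names,
            "species": norm.obs["species"] if "species" in norm.obs else "NA",
            "cluster": labels,
            "cell_type": [assign[c] for c in labels],
        },
        index=norm.obs_names,
    )
    return cells


def cell_type_ratios(cells: pd.DataFrame, drop_unassigned: bool = True) -> pd.DataFrame:
    """Species x cell-type proportion table; each species row sums to 1.

    Proportions are over annotated cells (``unassigned`` excluded by default).
    Species with zero annotated cells are omitted with a warning.
    """
    sub = cells[cells["cell_type"] != UNASSIGNED] if drop_unassigned else cells
    empty = set(cells["species"].unique()) - set(sub["species"].unique())
    for sp_id in sorted(empty):
        warnings.warn(f"species {sp_id!r} has no annotated cells; omitted", stacklevel=2)
    tab = pd.crosstab(sub["species"], sub["cell_type"])
    return tab.div(tab.sum(axis=1), axis=0)
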