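"""Cross-species comparison analyses.

Covers the downstream comparisons run on the pooled meta-gene matrix:
per-(species, cell type) pseudobulk profiles and their PCA; within-cell-type
cross-species differential expression; hypergeometric gene-set
overrepresentation; per-cell gene-family scores with a rank-sum group
contrast; the bulk FPKM differential-expression rule; and a transparent
mass-action ligand-receptor pathway-strength score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from ._stats import bh_adjust, rank_sum_test
from .cluster import rank_sum_de

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- pseudobulk


def pseudobulk_profiles(
    norm: AnnData, cells: pd.DataFrame, min_cells: int = 10
) -> pd.DataFrame:
    """Mean normalized expression per (species, cell type) group.

    Groups with fewer than ``min_cells`` cells are dropped with a warning.
    Returns a DataFrame indexed by (species, cell_type), one column per gene.
    """
    if cells.empty:
        raise ValueError("empty annotation table")
    x = sp.csr_matrix(norm.X)
    rows, index = [], []
    for (sp_id, ct), grp in cells.groupby(["species", "cell_type"], sort=True, observed=True):
        if len(grp) < min_cells:
            warnings.warn(
                f"group ({sp_id}, {ct}) has {len(grp)} < {min_cells} cells; dropped",
                stacklevel=2,
            )
            continue
        loc = norm.obs_names.get_indexer(grp.index)
        rows.append(np.asarray(x[loc].mean(axis=0)).ravel())
        index.append((sp_id, ct))
    if not rows:
        raise ValueError("no (species, cell type) group met the minimum cell count")
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["species", "cell_type"]),
        columns=norm.var_names,
    )


def pseudobulk_pca(profiles: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PCA of centered pseudobulk profiles (rows = (species, cell type))."""
    from sklearn.decomposition import PCA

    x = profiles.to_numpy() - profiles.to_numpy().mean(axis=0)
    n_components = min(n_components, min(x.shape) - 1)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(x)
    return pd.DataFrame(
        scores, index=profiles.index, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    )


# ------------------------------------------------------- cross-species DE


@dataclass
class DEThresholds:
    min_pct: float = 0.1
    min_log2fc: float = 0.25
    alpha: float = 0.05


def cross_species_de(
    norm: AnnData,
    cells: pd.DataFrame,
    cell_type: str,
    species_a: str,
    species_b: str,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Rank-sum DE between two species within one cell type.

    Positive log2FC means higher in ``species_a``. Uses the same machinery as
    one-vs-rest marker detection; BH adjustment over tested genes.
    """
    thresholds = thresholds or DEThresholds()
    sub = cells[cells["cell_type"] == cell_type]
    masks = {}
    for sp_id in (species_a, species_b):
        grp = sub[sub["species"] == sp_id]
        if len(grp) < 3:
            raise ValueError(
                f"species {sp_id!r} has {len(grp)} cells of type {cell_type!r} (need >= 3)"
            )
        mask = np.zeros(norm.n_obs, dtype=bool)
        mask[norm.obs_names.get_indexer(grp.index)] = True
        masks[sp_id] = mask
    tested, _ = rank_sum_de(
        norm,
        masks[species_a],
        masks[species_b],
        min_pct=thresholds.min_pct,
        min_log2fc=thresholds.min_log2fc,
    )
    tested = tested.copy()
    tested["direction"] = np.where(tested["log2fc"] > 0, f"up_{species_a}", f"up_{species_b}")
    return tested


# ------------------------------------------------------------- enrichment


def enrichment_test(
    hit_list: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation test per gene set.

    For a universe of N genes, a set of K members (intersected with the
    universe) and n hits with k overlapping the set, p = P(X >= k) for
    X ~ Hypergeom(N, K, n). BH adjustment across sets.
    """
    universe_set = {g.upper() for g in universe}
    hits = [g.upper() for g in hit_list]
    outside = sorted(set(hits) - universe_set)
    if outside:
        raise ValueError(f"hit genes absent from universe: {outside[:10]}")
    hits_set = set(hits)
    n_univ, n_hits = len(universe_set), len(hits_set)
    rows = []
    for name, members in gene_sets.items():
        k_set = {g.upper() for g in members} & universe_set
        overlap = len(k_set & hits_set)
        expected = n_hits * len(k_set) / n_univ if n_univ else 0.0
        p = stats.hypergeom.sf(overlap - 1, n_univ, len(k_set), n_hits) if overlap else 1.0
        rows.append((name, len(k_set), overlap, expected, min(1.0, float(p))))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "expected", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


# ------------------------------------------------------------ family score


def family_score(
    norm: AnnData,
    cells: pd.DataFrame,
    family: list[str],
    group_a: pd.Index | np.ndarray | None = None,
    group_b: pd.Index | np.ndarray | None = None,
) -> tuple[pd.Series, dict | None]:
    """Per-cell mean log-normalized expression over a gene family's members.

    The mean (not the sum) keeps families of different sizes comparable.
    If two cell groups (index arrays into ``norm.obs_names``) are given, the
    scores are contrasted by a two-sided rank-sum test and a summary dict
    (means, difference, p) is returned alongside.
    """
    genes = {g.upper(): i for i, g in enumerate(norm.var_names)}
    idx = [genes[g.upper()] for g in family if g.upper() in genes]
    missing = [g for g in family if g.upper() not in genes]
    if not idx:
        raise ValueError(f"no family member present in matrix; missing: {missing}")
    if missing:
        warnings.warn(f"family members not in matrix: {missing}", stacklevel=2)
    x = sp.csr_matrix(norm.X)[:, idx]
    scores = pd.Series(
        np.asarray(x.mean(axis=1)).ravel(), index=norm.obs_names, name="family_score"
    )
    contrast = None
    if group_a is not None and group_b is not None:
        a = scores.loc[group_a].to_numpy()[:, None]
        b = scores.loc[group_b].to_numpy()[:, None]
        _, p = rank_sum_test(a, b)
        contrast = {
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "difference": float(a.mean() - b.mean()),
            "p": float(p[0]),
        }
    return scores, contrast


# ---------------------------------------------------------------- bulk DE

UNEXPRESSED = "unexpressed"


def bulk_de(
    fpkm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fpkm_min: float = 1.0,
    log2fc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bulk FPKM differential expression rule.

    Genes whose larger group-mean FPKM is below ``fpkm_min`` are discarded as
    unexpressed (no p-value). For the rest, log2FC = log2((mean_a+1)/(mean_b+1))
    and p comes from a two-sided Welch t-test on log2(FPKM+1); a gene is
    ``up``/``down`` iff |log2FC| > ``log2fc_min`` and p < ``alpha``, else ``ns``.
    """
    for grp, name in ((group_a, "group_a"), (group_b, "group_b")):
        if len(grp) < 2:
            raise ValueError(f"{name} has {len(grp)} replicate(s); need >= 2 for the t-test")
        missing = [s for s in grp if s not in fpkm.columns]
        if missing:
            raise ValueError(f"samples {missing} not in FPKM table")
    a = fpkm[group_a].to_numpy(dtype=float)
    b = fpkm[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    expressed = np.maximum(mean_a, mean_b) >= fpkm_min
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    p = np.full(len(fpkm), np.nan)
    if expressed.any():
        res = stats.ttest_ind(
            np.log2(a[expressed] + 1.0), np.log2(b[expressed] + 1.0),
            axis=1, equal_var=False,
        )
        p[expressed] = res.pvalue
    p = np.where(np.isnan(p) & expressed, 1.0, p)  # zero-variance ties -> ns

    status = np.full(len(fpkm), "ns", dtype=object)
    status[~expressed] = UNEXPRESSED
    sig = expressed & (np.abs(log2fc) > log2fc_min) & (p < alpha)
    status[sig & (log2fc > 0)] = "up"
    status[sig & (log2fc < 0)] = "down"

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
            "status": status,
        },
        index=fpkm.index,
    )
    out.loc[~expressed, ["p"]] = np.nan
    out["p_adj"] = np.nan
    if expressed.any():
        out.loc[expressed, "p_adj"] = bh_adjust(out.loc[expressed, "p"].to_numpy())
    return out


# ------------------------------------------------- ligand-receptor strength


def lr_pathway_strength(
    norm: AnnData,
    cells: pd.DataFrame,
    pairs: pd.DataFrame,
    sender_types: list[str],
    receiver_types: list[str],
    species: list[str] | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mass-action ligand-receptor scoring per species.

    For each (ligand, receptor, pathway) row and each (sender type, receiver
    type) combination within one species, the pair score is
    ``mean(expm1 ligand in sender cells) * mean(expm1 receptor in receiver
    cells)``. Pathway strength is the sum of its pair scores over all
    combinations; per species the pathway strengths are normalized to sum 1
    ("relative strength"). Pairs whose ligand and receptor are both absent
    from the matrix are skipped with a warning; an absent ligand or receptor
    alone contributes 0.

    With ``n_permutations`` > 0, a per-(pair, species) permutation p-value is
    computed by shuffling cell-type labels within the species.

    Returns (pair_scores, pathway_strengths).
    """
    required = {"ligand", "receptor", "pathway"}
    if not required <= set(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    if (pairs["ligand"].str.upper() == pairs["receptor"].str.upper()).any():
        raise ValueError("ligand and receptor must differ")
    genes = {g.upper(): i for i, g in enumerate(norm.var_names)}
    species = species or sorted(cells["species"].unique())
    x = sp.csr_matrix(norm.X)
    rng = np.random.default_rng(seed)

    def group_mean(gene_idx: int | None, mask: np.ndarray) -> float:
        if gene_idx is None or not mask.any():
            return 0.0
        vals = np.asarray(x[mask, gene_idx].todense()).ravel()
        return float(np.expm1(vals).mean())

    pair_rows = []
    for sp_id in species:
        in_species = (cells["species"] == sp_id).to_numpy()
        type_masks = {}
        for t in set(sender_types) | set(receiver_types):
            sel = in_species & (cells["cell_type"] == t).to_numpy()
            mask = np.zeros(norm.n_obs, dtype=bool)
            mask[norm.obs_names.get_indexer(cells.index[sel])] = True
            type_masks[t] = mask
        for _, row in pairs.iterrows():
            li = genes.get(row["ligand"].upper())
            ri = genes.get(row["receptor"].upper())
            if li is None and ri is None:
                warnings.warn(
                    f"pair {row['ligand']}-{row['receptor']}: both genes absent; skipped",
                    stacklevel=2,
                )
                continue
            score = 0.0
            for st in sender_types:
                lmean = group_mean(li, type_masks[st])
                if lmean == 0.0:
                    continue
                for rt in receiver_types:
                    score += lmean * group_mean(ri, type_masks[rt])
            rec = {
                "species": sp_id,
                "ligand": row["ligand"],
                "receptor": row["receptor"],
                "pathway": row["pathway"],
                "score": score,
            }
            if n_permutations > 0:
                null = np.empty(n_permutations)
                labels = cells.loc[cells["species"] == sp_id, "cell_type"].to_numpy()
                idx_sp = norm.obs_names.get_indexer(cells.index[cells["species"] == sp_id])
                for b in range(n_permutations):
                    perm = rng.permutation(labels)
                    s = 0.0
                    for st in sender_types:
                        ms = np.zeros(norm.n_obs, dtype=bool)
                        ms[idx_sp[perm == st]] = True
                        lmean = group_mean(li, ms)
                        if lmean == 0.0:
                            continue
                        for rt in receiver_types:
                            mr = np.zeros(norm.n_obs, dtype=bool)
                            mr[idx_sp[perm == rt]] = True
                            s += lmean * group_mean(ri, mr)
                    null[b] = s
                rec["p_perm"] = float((1 + np.sum(null >= score)) / (1 + n_permutations))
            pair_rows.append(rec)

    pair_scores = pd.DataFrame(pair_rows)
    if pair_scores.empty:
        raise ValueError("no scorable ligand-receptor pair")
    strengths = (
        pair_scores.groupby(["species", "pathway"], observed=True)["score"].sum().reset_index()
    )
    strengths["relative_strength"] = strengths.groupby("species")["score"].transform(
        lambda s: s / s.sum() if s.sum() > 0 else 0.0
    )
    return pair_scores, strengths
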