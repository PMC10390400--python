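"""Project per-species count matrices onto the shared meta-gene space.

Aggregation sums raw UMI counts over all of a meta-gene's member symbols in a
species ("read counts combined across all manifestations"), before any
normalization. The operation conserves counts: for every cell the aggregated
column total equals the input total restricted to genes that map to some
meta-gene.

Count matrices are AnnData objects, cells x genes, with raw integer counts in
``.X`` (sparse), ``obs['species']`` / ``obs['barcode']`` and gene symbols in
``var_names``.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .orthology import MetaGeneTable

logger = logging.getLogger(__name__)


class MTXFormatError(ValueError):
    pass


def _open_maybe_gz(base: Path):
    if base.exists():
        return base.open("rb")
    gz = base.with_name(base.name + ".gz")
    if gz.exists():
        return gzip.open(gz, "rb")
    raise FileNotFoundError(f"neither {base} nor {gz} exists")


def read_mtx(directory, species: str | None = None) -> AnnData:
    """Read a 10x-style MTX triplet (matrix.mtx / features.tsv / barcodes.tsv).

    The matrix file is genes x cells (10x convention); the returned AnnData is
    cells x genes. Plain and gzipped triplets are both accepted.
    """
    directory = Path(directory)
    with _open_maybe_gz(directory / "matrix.mtx") as fh:
        m = sp.csr_matrix(scipy.io.mmread(fh)).T  # -> cells x genes
    with _open_maybe_gz(directory / "features.tsv") as fh:
        features = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    with _open_maybe_gz(directory / "barcodes.tsv") as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if features.empty or barcodes.empty:
        raise MTXFormatError(f"empty features or barcodes file in {directory}")
    genes = features.iloc[:, 0].tolist()
    cells = barcodes.iloc[:, 0].tolist()
    if m.shape != (len(cells), len(genes)):
        raise MTXFormatError(
            f"matrix shape {m.T.shape} (genes x cells) does not match "
            f"{len(genes)} features x {len(cells)} barcodes in {directory}"
        )
    if len(set(cells)) != len(cells):
        raise MTXFormatError(f"duplicate barcodes in {directory}")
    obs = pd.DataFrame({"barcode": cells}, index=cells)
    if species is not None:
        obs["species"] = species
    adata = AnnData(X=m.astype(np.int64), obs=obs, var=pd.DataFrame(index=genes))
    adata.obs_names_make_unique()
    return adata


def write_mtx(adata: AnnData, directory) -> None:
    """Write an AnnData as a plain 10x-style triplet (genes x cells on disk)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X).T
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat)
    pd.Series(adata.var_names).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs["barcode"] if "barcode" in adata.obs else adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def aggregate_counts(counts: AnnData, metagenes: MetaGeneTable, species: str) -> AnnData:
    """Sum raw counts over each meta-gene's member genes for one species.

    Output rows follow the meta-gene table order (identical across species).
    Genes not in any meta-gene are dropped; their summed counts are logged.
    Per-cell conservation holds exactly: aggregated totals equal input totals
    over mapped genes.
    """
    if species not in metagenes.species:
        raise ValueError(f"species {species!r} not in meta-gene table {metagenes.species}")
    members = metagenes.members_for_species(species)
    meta_ids = metagenes.meta_genes
    gene_index = {g.upper(): i for i, g in enumerate(counts.var_names)}

    rows, cols = [], []
    seen: dict[int, str] = {}
    for mi, mg in enumerate(meta_ids):
        for sym in members[mg]:
            gi = gene_index.get(sym.upper())
            if gi is None:
                continue
            if gi in seen and seen[gi] != mg:
                raise ValueError(
                    f"gene {counts.var_names[gi]!r} maps to meta-genes "
                    f"{seen[gi]!r} and {mg!r}; counts cannot be conserved"
                )
            if gi in seen:
                continue  # same symbol listed twice within one meta-gene
            seen[gi] = mg
            rows.append(mi)
            cols.append(gi)

    if not rows:
        raise ValueError(
            f"no overlap between matrix genes and meta-gene members for species "
            f"{species!r} — species mix-up?"
        )

    n_meta, n_genes = len(meta_ids), counts.n_vars
    indicator = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(n_meta, n_genes)
    )
    x = sp.csr_matrix(counts.X)
    agg = (indicator @ x.T).T.tocsr()  # cells x meta-genes

    unmapped = sorted(set(range(n_genes)) - set(cols))
    if unmapped:
        unmapped_total = int(x[:, unmapped].sum())
        logger.info(
            "aggregate_counts[%s]: dropped %d unmapped genes carrying %d counts",
            species,
            len(unmapped),
            unmapped_total,
        )
    obs = counts.obs.copy()
    if "species" not in obs:
        obs["species"] = species
    return AnnData(X=agg, obs=obs, var=pd.DataFrame(index=meta_ids))


def concat_species(matrices: list[AnnData]) -> AnnData:
    """Concatenate per-species meta-gene matrices into one pooled matrix.

    All inputs must share the exact meta-gene order (no silent reindexing).
    Barcodes are suffixed with the species id so they stay unique.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    ref_genes = list(matrices[0].var_names)
    for m in matrices[1:]:
        if list(m.var_names) != ref_genes:
            raise ValueError("gene order mismatch between matrices; aggregate against the "
                             "same meta-gene table first")
    xs, obs_frames = [], []
    for m in matrices:
        if "species" not in m.obs:
            raise ValueError("each matrix needs obs['species']")
        sp_id = m.obs["species"].iloc[0]
        obs = m.obs.copy()
        barcodes = obs["barcode"] if "barcode" in obs else pd.Series(obs.index, index=obs.index)
        obs["barcode"] = barcodes.astype(str)
        obs.index = [f"{b}_{s}" for b, s in zip(obs["barcode"], obs["species"])]
        obs_frames.append(obs)
        xs.append(sp.csr_matrix(m.X))
        logger.info("concat_species: %s contributes %d cells", sp_id, m.n_obs)
    x = sp.vstack(xs).tocsr()
    obs = pd.concat(obs_frames)
    if obs.index.duplicated().any():
        raise ValueError("duplicate (barcode, species) pairs after suffixing")
    return AnnData(X=x, obs=obs, var=pd.DataFrame(index=ref_genes))


def split_species(adata: AnnData) -> dict[str, AnnData]:
    """Inverse of :func:`concat_species` (up to the barcode suffix)."""
    out = {}
    for sp_id in adata.obs["species"].unique():
        sub = adata[adata.obs["species"] == sp_id].copy()
        sub.obs.index = sub.obs["barcode"].astype(str)
        out[sp_id] = sub
    return out
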