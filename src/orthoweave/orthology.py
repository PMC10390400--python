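"""Reference-anchored ortholog "meta-gene" table construction.

Cross-species expression comparison needs a shared gene space. Following the
standard BioMart-anchored approach, every gene of a designated reference
species (human here) seeds one candidate *meta-gene*; homolog symbols of the
other species attach to it. A meta-gene covered in every required species is
retained; groups where each species contributes exactly one symbol are
classed ``one2one_all`` ("1-1-1-1" orthologs), groups where some species
contributes paralogs are classed ``one_to_many`` ("1-many").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

ONE2ONE = "one2one_all"
ONE_TO_MANY = "one_to_many"

HOMOLOGY_COLUMNS = ["ref_gene", "species", "homolog_symbol"]


class HomologyFormatError(ValueError):
    """Raised when a homology file does not match a known dialect."""


@dataclass
class MetaGeneEntry:
    """One ortholog group anchored on a reference gene symbol."""

    meta_gene: str
    members: dict[str, list[str]]
    orthology_class: str
    n_species_covered: int


@dataclass
class MetaGeneTable:
    """Ordered collection of meta-gene entries (reference-symbol lexicographic)."""

    entries: list[MetaGeneEntry] = field(default_factory=list)
    species: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def meta_genes(self) -> list[str]:
        return [e.meta_gene for e in self.entries]

    def members_for_species(self, species: str) -> dict[str, list[str]]:
        """Map meta_gene -> member symbols for one species."""
        return {e.meta_gene: e.members.get(species, []) for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        """Long table with one row per (meta_gene, species, member)."""
        rows = []
        for e in self.entries:
            for sp in self.species:
                for m in e.members.get(sp, []):
                    rows.append((e.meta_gene, sp, m, e.orthology_class))
        return pd.DataFrame(rows, columns=["meta_gene", "species", "member", "orthology_class"])

    def flatten(self) -> pd.DataFrame:
        """The table's own records in homology-table form (for idempotent rebuilds)."""
        df = self.to_frame()
        return df.rename(columns={"meta_gene": "ref_gene", "member": "homolog_symbol"})[
            HOMOLOGY_COLUMNS
        ]


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["ref_gene"] = df["ref_gene"].astype(str).str.upper()
    df["homolog_symbol"] = df["homolog_symbol"].astype(str).str.upper()
    df["species"] = df["species"].astype(str)
    return df


def read_homology(
    path,
    species: list[str] | None = None,
    homology_types: set[str] | None = None,
) -> pd.DataFrame:
    """Read a homology table in long or wide (BioMart-export) dialect.

    Long dialect: columns ``ref_gene``, ``species``, ``homolog_symbol``
    (one row per homolog pair). Wide dialect: a ``ref_gene`` column plus
    ``<species>_gene_name`` columns and optional ``<species>_homology_type``
    columns, one row per homolog combination — the layout of a multi-species
    BioMart export.

    Parameters
    ----------
    path
        TSV file path.
    species
        Configured species ids; when given, unknown species in the file raise.
    homology_types
        Optional homology-type filter (e.g. ``{"ortholog_one2one"}``); only
        effective in the wide dialect, which carries type columns. Default off.

    Returns
    -------
    DataFrame with columns ``ref_gene, species, homolog_symbol``, deduplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    if set(HOMOLOGY_COLUMNS) <= cols:
        long = df[HOMOLOGY_COLUMNS].dropna()
    elif "ref_gene" in cols:
        sp_cols = [c for c in df.columns if c.endswith("_gene_name")]
        if not sp_cols:
            raise HomologyFormatError(
                f"wide homology file needs <species>_gene_name columns, got {sorted(cols)}"
            )
        frames = []
        for c in sp_cols:
            sp = c[: -len("_gene_name")]
            sub = df[["ref_gene", c]].dropna().rename(columns={c: "homolog_symbol"})
            type_col = f"{sp}_homology_type"
            if homology_types is not None and type_col in cols:
                keep = df.loc[sub.index, type_col].isin(homology_types)
                sub = sub[keep]
            sub["species"] = sp
            frames.append(sub[HOMOLOGY_COLUMNS])
        long = pd.concat(frames, ignore_index=True)
    else:
        raise HomologyFormatError(
            f"homology file must have columns {HOMOLOGY_COLUMNS} (long) or a "
            f"ref_gene + <species>_gene_name layout (wide); got {sorted(cols)}"
        )

    long = _normalize(long)
    n_raw = len(long)
    long = long.drop_duplicates(HOMOLOGY_COLUMNS).reset_index(drop=True)
    n_dup = n_raw - len(long)
    if n_dup:
        logger.warning("read_homology: dropped %d duplicate records (%d kept)", n_dup, len(long))
    logger.info("read_homology: %d homolog records", len(long))

    if species is not None:
        unknown = sorted(set(long["species"]) - set(species))
        if unknown:
            raise ValueError(
                f"unknown species id(s) {unknown}; configured species: {sorted(species)}"
            )
    return long


def build_metagene_table(
    homology: pd.DataFrame,
    species: list[str],
    min_species: int | None = None,
    many_to_many_policy: str = "smallest_ref",
) -> MetaGeneTable:
    """Aggregate homolog records into the reference-anchored meta-gene table.

    Each reference gene seeds one candidate meta-gene collecting all homolog
    symbols attached to it; candidates covered in fewer than ``min_species``
    species (default: all) are dropped. A homolog symbol claimed by several
    reference genes within one species (a many-to-many homology) is resolved by
    ``many_to_many_policy``:

    - ``smallest_ref`` (default): keep it under the lexicographically smallest
      reference gene and log the conflict;
    - ``duplicate``: keep it under every claimant (double counting downstream);
    - ``drop``: remove the symbol from all claimants.
    """
    if not species:
        raise ValueError("species list must be non-empty")
    if min_species is None:
        min_species = len(species)
    if many_to_many_policy not in {"smallest_ref", "duplicate", "drop"}:
        raise ValueError(f"unknown many-to-many policy {many_to_many_policy!r}")

    hom = _normalize(homology)
    hom = hom[hom["species"].isin(species)]
    hom = hom.drop_duplicates(HOMOLOGY_COLUMNS)

    # many-to-many resolution: within a species, one homolog symbol may be
    # claimed by several reference genes
    claims = hom.groupby(["species", "homolog_symbol"])["ref_gene"].nunique()
    conflicted = claims[claims > 1]
    if len(conflicted) and many_to_many_policy != "duplicate":
        logger.warning(
            "build_metagene_table: %d many-to-many homolog symbols resolved by policy %r",
            len(conflicted),
            many_to_many_policy,
        )
        if many_to_many_policy == "smallest_ref":
            winner = hom.groupby(["species", "homolog_symbol"])["ref_gene"].transform("min")
            hom = hom[hom["ref_gene"] == winner]
        else:  # drop
            key = hom.set_index(["species", "homolog_symbol"]).index
            hom = hom[~key.isin(conflicted.index)]

    entries: list[MetaGeneEntry] = []
    n_excluded = 0
    for ref in sorted(hom["ref_gene"].unique()):
        sub = hom[hom["ref_gene"] == ref]
        members = {
            sp: sorted(sub.loc[sub["species"] == sp, "homolog_symbol"].unique())
            for sp in species
        }
        members = {sp: m for sp, m in members.items() if m}
        covered = len(members)
        if covered < min_species:
            n_excluded += 1
            continue
        cls = ONE2ONE if all(len(m) == 1 for m in members.values()) else ONE_TO_MANY
        entries.append(MetaGeneEntry(ref, members, cls, covered))
    if n_excluded:
        logger.info(
            "build_metagene_table: excluded %d reference genes covered in < %d species",
            n_excluded,
            min_species,
        )
    return MetaGeneTable(entries=entries, species=list(species))


def classify_summary(table: MetaGeneTable) -> dict[str, int]:
    """Counts of retained meta-genes per orthology class."""
    n1 = sum(1 for e in table if e.orthology_class == ONE2ONE)
    n2 = sum(1 for e in table if e.orthology_class == ONE_TO_MANY)
    return {ONE2ONE: n1, ONE_TO_MANY: n2, "total": n1 + n2}


def write_metagene_table(table: MetaGeneTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_metagene_table(path, species: list[str]) -> MetaGeneTable:
    """Rebuild a MetaGeneTable from its long-TSV form."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    flat = df.rename(columns={"meta_gene": "ref_gene", "member": "homolog_symbol"})
    return build_metagene_table(flat[HOMOLOGY_COLUMNS], species, min_species=1)
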