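"""Synthetic four-species gastric-antrum data with planted ground truth.

The generator emulates the structure of the study design that the pipeline
targets: homology tables anchored on a reference species (with paralog
expansions and missing homologs), per-species single-cell UMI matrices with
shared epithelial cell types plus one species-private type, an immune gene
program elevated in one species, mitochondrial count fractions, dropout, and
a bulk FPKM table with planted fold changes (a TNFa-like two-group contrast).

Counts follow a negative-binomial model: per-cell library sizes are
log-normal, a cell's expected expression is the shared baseline gene weights
multiplied by its type's marker-program boost (and the immune boost in the
boosted species), mitochondrial genes receive the cell's drawn mito fraction
of its library, and paralogous homologs of one reference gene split that
gene's expectation uniformly — so meta-gene aggregation approximately
inverts the split.

Every generated artifact is paired with a ``SyntheticTruth`` record; the
pipeline itself never reads the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .cluster import DEFAULT_MARKER_PANEL
from .harmonize import write_mtx

REFERENCE_INDEX = 0

#: Fixed mitochondrial gene subset, identical symbols in every species.
MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
]

#: Immune program members (elevated in the boosted species). Includes the
#: RANKL ligand/receptor pair so one signaling pathway is planted as more
#: active in that species.
DEFAULT_IMMUNE_GENES = [
    "IGHM", "IGKC", "IGLL1", "JCHAIN", "CD74", "BPI", "FADD", "CHID1",
    "GPER1", "CD79A", "CD40", "IL17D", "TNFSF11", "TNFRSF11A",
] + [f"IMM{i:03d}" for i in range(1, 12)]

#: Ligand-receptor pair table bundled with the simulation (pathway labels
#: follow the usual cell-communication nomenclature).
DEFAULT_LR_PAIRS = pd.DataFrame(
    [
        ("GZMA", "F2R", "PAR"),
        ("GZMA", "F2RL3", "PAR"),
        ("CD70", "CD27", "CD70"),
        ("TNFSF11", "TNFRSF11A", "RANKL"),
        ("IL17D", "IL17RA", "IL17"),
        ("NRG1", "ERBB3", "EGF"),
    ],
    columns=["ligand", "receptor", "pathway"],
)

_LR_ONLY_GENES = ["GZMA", "F2R", "F2RL3", "CD70", "CD27", "IL17RA", "NRG1", "ERBB3"]


@dataclass
class CellTypeSpec:
    """One simulated cell type: its marker program and per-species abundance."""

    name: str
    n_cells: int | dict[str, int]
    markers: list[str]
    program_size: int = 20
    log2_boost: float = 3.0

    def cells_for(self, species: str) -> int:
        n = self.n_cells[species] if isinstance(self.n_cells, dict) else self.n_cells
        if n <= 0:
            raise ValueError(f"cell count for {self.name!r}/{species!r} must be > 0")
        return int(n)


def default_cell_types() -> list[CellTypeSpec]:
    """The study-like default: seven shared antral types + the pig-private one.

    Pit mucous and proliferative cells dominate the rodents, basal gland
    mucous cells are commoner in human and pig, and parietal cells are scarce
    in pig — echoing the composition differences the comparison stage should
    surface.
    """
    p = DEFAULT_MARKER_PANEL
    return [
        CellTypeSpec("pit mucous cell",
                     {"human": 200, "pig": 200, "rat": 260, "mouse": 260},
                     p["pit mucous cell"]),
        CellTypeSpec("proliferative cell",
                     {"human": 150, "pig": 150, "rat": 200, "mouse": 200},
                     p["proliferative cell"]),
        CellTypeSpec("chief cell", 150, p["chief cell"]),
        CellTypeSpec("tuft cell", 80, p["tuft cell"]),
        CellTypeSpec("endocrine cell", 80, p["endocrine cell"]),
        CellTypeSpec("parietal cell",
                     {"human": 100, "pig": 50, "rat": 100, "mouse": 100},
                     p["parietal cell"]),
        CellTypeSpec("BGMC",
                     {"human": 180, "pig": 180, "rat": 100, "mouse": 100},
                     p["BGMC"]),
        CellTypeSpec("F3+ cell", 160, p["F3+ cell"]),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic four-species experiment."""

    species_names: list[str] = field(default_factory=lambda: ["human", "pig", "rat", "mouse"])
    n_ref_genes: int = 1000
    paralog_rate: float = 0.10
    missing_rate: float = 0.05
    cell_types: list[CellTypeSpec] = field(default_factory=default_cell_types)
    private_type: str = "F3+ cell"
    private_type_species: str = "pig"
    immune_program: tuple[str, str, float] = ("immune", "pig", 2.0)
    immune_genes: list[str] = field(default_factory=lambda: list(DEFAULT_IMMUNE_GENES))
    mito_beta: tuple[float, float] = (2.0, 38.0)
    dropout_rate: float = 0.10
    dispersion: float = 0.10
    library_median: float = 5000.0
    library_sigma: float = 0.3
    bulk_n_de: int = 50
    bulk_log2fc: float = 2.0
    bulk_noise_sd: float = 0.10
    seed: int = 0

    @property
    def reference(self) -> str:
        return self.species_names[REFERENCE_INDEX]

    def __post_init__(self):
        for name, rate in (
            ("paralog_rate", self.paralog_rate),
            ("missing_rate", self.missing_rate),
            ("dropout_rate", self.dropout_rate),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.paralog_rate + self.missing_rate > 1:
            raise ValueError("paralog_rate + missing_rate must not exceed 1")
        if self.private_type_species not in self.species_names:
            raise ValueError(
                f"private_type_species {self.private_type_species!r} "
                f"not in {self.species_names}"
            )
        if self.immune_program[1] not in self.species_names:
            raise ValueError("immune program species not in species_names")
        if self.n_ref_genes < len(self._named_genes()):
            raise ValueError(
                f"n_ref_genes={self.n_ref_genes} too small for the "
                f"{len(self._named_genes())} named genes"
            )

    def _named_genes(self) -> list[str]:
        named: list[str] = list(MITO_GENES)
        for ct in self.cell_types:
            named += [g for g in ct.markers if g not in named]
        named += [g for g in self.immune_genes if g not in named]
        named += [g for g in _LR_ONLY_GENES if g not in named]
        return named

    def gene_names(self) -> list[str]:
        """Reference gene universe: named genes padded with generic symbols."""
        named = self._named_genes()
        pad = [f"G{i:04d}" for i in range(1, self.n_ref_genes - len(named) + 1)]
        return named + pad

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SyntheticTruth:
    """Planted ground truth; emitted alongside data, never consumed by the pipeline."""

    cell_types: dict[str, list[str]] = field(default_factory=dict)
    gene_programs: dict[str, list[str]] = field(default_factory=dict)
    metagene_of: dict[str, dict[str, str]] = field(default_factory=dict)
    immune: dict = field(default_factory=dict)
    planted_lr_pathway: str = "RANKL"
    bulk_de_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _protected(config: SimulationConfig) -> set[str]:
    """Genes exempt from the missing-homolog draw (panels must resolve everywhere)."""
    prot = set(MITO_GENES)
    for ct in config.cell_types:
        prot |= set(ct.markers)
    prot |= set(config.immune_genes) | set(_LR_ONLY_GENES)
    return prot


def generate_homology(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit a reference-anchored homology table with paralogs and gaps.

    For each (reference gene, non-reference species) pair: no homolog with
    probability ``missing_rate``, 2-3 paralogous homologs with probability
    ``paralog_rate``, one homolog otherwise. The reference species always
    contributes the reference gene itself; mitochondrial genes keep their
    symbol in every species; marker-panel and program genes are never missing.
    """
    rng = config._rng(1)
    genes = config.gene_names()
    protected = _protected(config)
    truth = SyntheticTruth()
    rows = []
    for g in genes:
        for s in config.species_names:
            if s == config.reference or g in MITO_GENES:
                symbols = [g]
            else:
                u = rng.random()
                if u < config.missing_rate and g not in protected:
                    symbols = []
                elif u < config.missing_rate + config.paralog_rate:
                    k = int(rng.integers(2, 4))
                    symbols = [f"{g}-{s.upper()}P{i}" for i in range(1, k + 1)]
                else:
                    symbols = [f"{g}-{s.upper()}"]
            for sym in symbols:
                rows.append((g, s, sym))
                truth.metagene_of.setdefault(s, {})[sym] = g
    homology = pd.DataFrame(rows, columns=["ref_gene", "species", "homolog_symbol"])
    return homology, truth


def _program_genes(config: SimulationConfig) -> dict[str, list[str]]:
    """Marker programs: named markers plus disjoint generic program genes."""
    rng = config._rng(2)
    genes = config.gene_names()
    reserved = set(_protected(config))
    pool = [g for g in genes if g not in reserved]
    programs: dict[str, list[str]] = {}
    for ct in config.cell_types:
        take = min(ct.program_size, len(pool))
        picked = [pool[i] for i in sorted(rng.choice(len(pool), size=take, replace=False))]
        pool = [g for g in pool if g not in set(picked)]
        programs[ct.name] = list(ct.markers) + picked
    return programs


def _base_weights(config: SimulationConfig) -> np.ndarray:
    """Shared baseline expression weights; program/immune/LR genes clamped to
    at least the median so planted effects sit on detectable expression."""
    rng = config._rng(3)
    genes = config.gene_names()
    w = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    med = float(np.median(w))
    keep_high = _protected(config)
    for i, g in enumerate(genes):
        if g in keep_high and w[i] < med:
            w[i] = med
    return w


def generate_counts(
    config: SimulationConfig, homology: pd.DataFrame
) -> tuple[dict[str, AnnData], SyntheticTruth]:
    """Draw per-species UMI matrices from the negative-binomial model."""
    expected = {"ref_gene", "species", "homolog_symbol"}
    if not expected <= set(homology.columns):
        raise ValueError(f"homology table needs columns {sorted(expected)}")
    hom_species = set(homology["species"].unique())
    if hom_species != set(config.species_names):
        raise ValueError(
            f"homology species {sorted(hom_species)} do not match config "
            f"{config.species_names}"
        )
    genes = config.gene_names()
    if not set(homology["ref_gene"]) <= set(genes):
        raise ValueError("homology table references genes outside this config")

    gene_idx = {g: i for i, g in enumerate(genes)}
    programs = _program_genes(config)
    base = _base_weights(config)
    immune_name, immune_species, immune_log2 = config.immune_program
    immune_idx = [gene_idx[g] for g in config.immune_genes]
    mito_mask = np.array([g in set(MITO_GENES) for g in genes])
    mito_w = np.where(mito_mask, base, 0.0)
    mito_w = mito_w / mito_w.sum()

    rng = config._rng(4)
    r = 1.0 / config.dispersion
    truth = SyntheticTruth(gene_programs={**programs, immune_name: list(config.immune_genes)})
    truth.immune = {
        "program": immune_name,
        "species": immune_species,
        "log2_boost": immune_log2,
        "genes": list(config.immune_genes),
    }

    matrices: dict[str, AnnData] = {}
    for s in config.species_names:
        sub = homology[homology["species"] == s]
        members: dict[str, list[str]] = {}
        for g, sym in zip(sub["ref_gene"], sub["homolog_symbol"]):
            members.setdefault(g, []).append(sym)
        species_genes, split_rows, split_cols, split_vals = [], [], [], []
        for g in genes:  # fixed reference order
            for sym in members.get(g, []):
                split_rows.append(len(species_genes))
                split_cols.append(gene_idx[g])
                split_vals.append(1.0 / len(members[g]))
                species_genes.append(sym)
        split = sp.csr_matrix(
            (split_vals, (split_rows, split_cols)), shape=(len(species_genes), len(genes))
        )

        type_specs = [
            ct for ct in config.cell_types
            if ct.name != config.private_type or s == config.private_type_species
        ]
        labels: list[str] = []
        mean_blocks = []
        for ct in type_specs:
            n = ct.cells_for(s)
            boost = np.ones(len(genes))
            prog = [gene_idx[g] for g in programs[ct.name]]
            boost[prog] *= 2.0**ct.log2_boost
            if s == immune_species:
                boost[immune_idx] *= 2.0**immune_log2
            w = base * boost
            w[mito_mask] = 0.0
            w = w / w.sum()

            lib = rng.lognormal(np.log(config.library_median), config.library_sigma, size=n)
            mfrac = rng.beta(*config.mito_beta, size=n)
            ref_mean = (
                np.outer(lib * (1 - mfrac), w) + np.outer(lib * mfrac, mito_w)
            )  # cells x ref genes
            mean_blocks.append(ref_mean)
            labels += [ct.name] * n

        ref_means = np.vstack(mean_blocks)
        mu = ref_means @ split.T.toarray()  # cells x species genes
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
        if config.dropout_rate > 0:
            keep = rng.random(counts.shape) >= config.dropout_rate
            counts = counts * keep
        barcodes = [f"C{i:05d}" for i in range(counts.shape[0])]
        obs = pd.DataFrame({"barcode": barcodes, "species": s}, index=barcodes)
        matrices[s] = AnnData(
            X=sp.csr_matrix(counts.astype(np.int64)),
            obs=obs,
            var=pd.DataFrame(index=species_genes),
        )
        truth.cell_types[s] = labels
    return matrices, truth


def generate_bulk(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Log-normal FPKM, 2 groups (control / tnfa) x 2 replicates per species.

    ``bulk_n_de`` genes drawn from the moderately expressed pool get a
    ``bulk_log2fc`` boost in the tnfa group; the truth lists them.
    """
    rng = config._rng(5)
    genes = config.gene_names()
    base = rng.lognormal(mean=np.log(8.0), sigma=1.5, size=len(genes))
    eligible = np.flatnonzero(base >= 2.0)
    n_de = min(config.bulk_n_de, len(eligible))
    de_idx = rng.choice(eligible, size=n_de, replace=False) if n_de else np.array([], int)
    fold = np.ones(len(genes))
    fold[de_idx] = 2.0**config.bulk_log2fc

    cols = {}
    for s in config.species_names:
        for group, f in (("control", np.ones(len(genes))), ("tnfa", fold)):
            for rep in (1, 2):
                noise = rng.normal(0.0, config.bulk_noise_sd, size=len(genes))
                cols[f"{s}_{group}_{rep}"] = base * f * 2.0**noise
    fpkm = pd.DataFrame(cols, index=genes)
    truth = SyntheticTruth(bulk_de_genes=[genes[i] for i in sorted(de_idx)])
    return fpkm, truth


def write_simulation(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate everything and write it to ``out_dir`` in plain-text formats.

    Layout: ``homology.tsv``, per-species MTX triplets under ``counts/<sp>/``,
    ``bulk_fpkm.tsv``, ``lr_pairs.tsv``, ``marker_panel.json``, ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    homology, truth_h = generate_homology(config)
    homology.to_csv(out / "homology.tsv", sep="\t", index=False)
    matrices, truth_c = generate_counts(config, homology)
    for s, adata in matrices.items():
        write_mtx(adata, out / "counts" / s)
    bulk, truth_b = generate_bulk(config)
    bulk.to_csv(out / "bulk_fpkm.tsv", sep="\t", index_label="gene")
    DEFAULT_LR_PAIRS.to_csv(out / "lr_pairs.tsv", sep="\t", index=False)
    (out / "marker_panel.json").write_text(json.dumps(DEFAULT_MARKER_PANEL, indent=1))
    truth = SyntheticTruth(
        cell_types=truth_c.cell_types,
        gene_programs=truth_c.gene_programs,
        metagene_of=truth_h.metagene_of,
        immune=truth_c.immune,
        planted_lr_pathway=truth_c.planted_lr_pathway,
        bulk_de_genes=truth_b.bulk_de_genes,
    )
    (out / "truth.json").write_text(truth.to_json())
    return {
        "homology": out / "homology.tsv",
        "counts": out / "counts",
        "bulk": out / "bulk_fpkm.tsv",
        "lr_pairs": out / "lr_pairs.tsv",
        "truth": out / "truth.json",
    }
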