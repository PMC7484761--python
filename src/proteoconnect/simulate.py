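"""Synthetic study, ortholog-map, compound-database and gene-set generators.

Every downstream stage of the pipeline is testable against *planted ground
truth* produced here:

* :func:`generate_study` builds a proteins x samples intensity table for the
  four-arm design (WT, DKD, DKD+R, WT+R) with planted disease effects, a
  drug-reversed subset, a non-disease-specific drug-responsive subset,
  missing-not-at-random dropout and contaminant/peptide annotation.
* :func:`generate_ortholog_map` builds a mouse protein -> human gene symbol
  table (default 1:1 by uppercasing, with configurable unmapped and
  one-to-many rates).
* :func:`generate_compound_db` builds a compound-signature database of full
  gene rankings with one planted signature *reverser* and one *mimic* among
  uniformly random decoys.
* :func:`generate_gene_sets` builds a GMT-style collection with one set
  planted from a chosen gene list.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CompoundDbConfig, ConfigError, StudyConfig
from .quant import ProteinQuantTable


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth labels for a synthetic study.

    ``rs_true`` holds proteins whose disease effect is counter-regulated by
    the drug in diabetic animals only; ``nonspecific_true`` holds proteins
    whose drug response also occurs in non-diabetic animals (and should be
    filtered out of both final signatures); ``ramipril_only_true`` holds
    proteins with a drug effect but no disease effect.
    """

    dkd_true_up: frozenset[str] = frozenset()
    dkd_true_down: frozenset[str] = frozenset()
    rs_true: frozenset[str] = frozenset()
    nonspecific_true: frozenset[str] = frozenset()
    ramipril_only_true: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        dkd = self.dkd_true_up | self.dkd_true_down
        if self.dkd_true_up & self.dkd_true_down:
            raise ValueError("a protein cannot be both up and down")
        if not (self.rs_true | self.nonspecific_true) <= dkd:
            raise ValueError("rs/nonspecific truth sets must be subsets of the DKD truth")
        if self.rs_true & self.nonspecific_true:
            raise ValueError("rs_true and nonspecific_true must be disjoint")

    @property
    def dkd_true(self) -> frozenset[str]:
        return self.dkd_true_up | self.dkd_true_down

    @property
    def ri_true(self) -> frozenset[str]:
        """Disease proteins with no drug response anywhere (drug-insensitive)."""
        return self.dkd_true - self.rs_true - self.nonspecific_true


def generate_study(config: StudyConfig) -> tuple[ProteinQuantTable, GroundTruth]:
    """Generate a quant table with planted effects and its ground truth.

    Effects are planted only on rows that survive the contaminant and
    two-peptide filters, so the truth sets are recoverable in principle;
    contaminant rows still receive ordinary intensities (removing them is
    the preprocessing filter's job).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    groups = list(config.groups)
    if len(groups) != 4:
        raise ConfigError("generate_study expects exactly 4 groups (control, disease, disease+drug, control+drug)")
    g_wt, g_dkd, g_dkdr, g_wtr = groups

    protein_ids = np.array([f"P{i:05d}" for i in range(n)])
    gene_symbols = np.array([f"Gp{i:05d}" for i in range(n)])

    contaminant = rng.random(n) < config.frac_contaminant
    n_peptides = np.maximum(rng.poisson(config.peptide_lambda, size=n), 1)

    eligible = np.flatnonzero(~contaminant & (n_peptides >= 2))
    n_planted = config.n_dkd_effect + config.n_ramipril_only
    if n_planted > eligible.size:
        raise ConfigError(
            f"cannot plant {n_planted} effects among {eligible.size} eligible proteins"
        )
    planted = rng.choice(eligible, size=n_planted, replace=False)
    dkd_idx = planted[: config.n_dkd_effect]
    ramipril_only_idx = planted[config.n_dkd_effect:]

    lo, hi = config.effect_log2_range
    effect = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=dkd_idx.size)
    effect[dkd_idx] = signs * rng.uniform(lo, hi, size=dkd_idx.size)

    # Disjoint drug-sensitive subsets among the disease proteins.
    n_rs = int(round(config.frac_rs * dkd_idx.size))
    n_ns = int(round(config.frac_nonspecific * dkd_idx.size))
    shuffled = rng.permutation(dkd_idx)
    rs_idx = shuffled[:n_rs]
    ns_idx = shuffled[n_rs:n_rs + n_ns]

    f_lo, f_hi = config.rs_reversal_range
    reversal = np.zeros(n)
    reversal[rs_idx] = rng.uniform(f_lo, f_hi, size=rs_idx.size)
    reversal[ns_idx] = rng.uniform(f_lo, f_hi, size=ns_idx.size)

    drug_only = np.zeros(n)
    if ramipril_only_idx.size:
        drug_only[ramipril_only_idx] = (
            rng.choice([-1.0, 1.0], size=ramipril_only_idx.size)
            * rng.uniform(max(lo, 1e-12), hi, size=ramipril_only_idx.size)
        )

    # Per-group mean shifts on the log2 scale.  The disease effect is present
    # in both diabetic arms; counter-regulation subtracts (a fraction of) it
    # in DKD+R, and for the non-specific subset the same drug response also
    # appears in WT+R.
    shift = {g: np.zeros(n) for g in groups}
    shift[g_dkd] = effect.copy()
    shift[g_dkdr] = effect - reversal * effect + drug_only
    shift[g_wtr] = drug_only.copy()
    shift[g_wtr][ns_idx] += -reversal[ns_idx] * effect[ns_idx]

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    samples: list[str] = []
    design: list[str] = []
    columns: dict[str, np.ndarray] = {}
    for g in groups:
        for rep in range(1, config.n_replicates + 1):
            name = f"{g}_{rep}"
            x = baseline + shift[g] + rng.normal(0.0, config.noise_log2_sd, size=n)
            p_missing = 1.0 / (1.0 + np.exp((x - config.mnar_midpoint) / config.mnar_slope))
            drop = rng.random(n) < p_missing
            intensity = np.power(2.0, x)
            intensity[drop] = np.nan
            columns[name] = intensity
            samples.append(name)
            design.append(g)

    data = pd.DataFrame(columns, index=pd.Index(protein_ids, name="protein_id"))
    meta = pd.DataFrame(
        {
            "gene_symbol": gene_symbols,
            "n_peptides": n_peptides.astype(int),
            "contaminant": contaminant,
        },
        index=data.index,
    )
    table = ProteinQuantTable(
        data=data, meta=meta, design=pd.Series(design, index=samples, name="group")
    )

    ids = protein_ids
    truth = GroundTruth(
        dkd_true_up=frozenset(ids[i] for i in dkd_idx if effect[i] > 0),
        dkd_true_down=frozenset(ids[i] for i in dkd_idx if effect[i] < 0),
        rs_true=frozenset(ids[i] for i in rs_idx),
        nonspecific_true=frozenset(ids[i] for i in ns_idx),
        ramipril_only_true=frozenset(ids[i] for i in ramipril_only_idx),
    )
    return table, truth


# -- ortholog map ----------------------------------------------------------------

def generate_ortholog_map(
    protein_ids,
    gene_symbols=None,
    frac_unmapped: float = 0.0,
    frac_multi: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mouse protein -> human gene symbol mapping table.

    Default behaviour is a clean 1:1 map: the human symbol is the uppercased
    mouse gene symbol (mouse symbols are capitalised, human ones all-caps —
    e.g. Nphs2 -> NPHS2).  ``frac_unmapped`` ids get no row at all and
    ``frac_multi`` ids get a second human target (paralog-style ambiguity).
    """
    protein_ids = list(protein_ids)
    if not protein_ids:
        raise ValueError("protein id list must be non-empty")
    if gene_symbols is None:
        gene_symbols = protein_ids
    gene_symbols = list(gene_symbols)
    if len(gene_symbols) != len(protein_ids):
        raise ValueError("gene_symbols must parallel protein_ids")
    rng = np.random.default_rng(seed)
    rows = []
    for pid, gene in zip(protein_ids, gene_symbols):
        u = rng.random()
        if u < frac_unmapped:
            continue
        human = str(gene).upper()
        rows.append((pid, gene, human))
        if rng.random() < frac_multi:
            rows.append((pid, gene, human + "B"))
    return pd.DataFrame(rows, columns=["mouse_protein_id", "mouse_gene", "human_gene"])


# -- compound-signature database --------------------------------------------------

def generate_compound_db(config: CompoundDbConfig, query) -> list:
    """Synthetic compound-signature database with a planted reverser and mimic.

    ``query`` is a :class:`~proteoconnect.idmap.QuerySignature` (or any object
    with ``up_genes``/``down_genes`` sets).  The universe consists of the
    query genes padded with filler symbols up to ``n_genes``.

    The reverser ranks the query's *down* genes near the top and its *up*
    genes near the bottom of every instance (each signature gene is relocated
    to a uniformly random position with probability ``reverser_noise``); the
    mimic does the opposite; all remaining compounds are uniform decoys.
    """
    from .connectivity import InstanceProfile

    up = sorted(query.up_genes)
    down = sorted(query.down_genes)
    sig_size = len(up) + len(down)
    if sig_size == 0:
        raise ValueError("query signature is empty")
    if config.n_genes < 2 * sig_size:
        raise ConfigError(
            f"n_genes={config.n_genes} must be >= 2 x signature size ({sig_size})"
        )
    universe = list(dict.fromkeys(up + down))
    filler = [f"CG{i:05d}" for i in range(config.n_genes)]
    for gene in filler:
        if len(universe) == config.n_genes:
            break
        if gene not in query.up_genes and gene not in query.down_genes:
            universe.append(gene)
    universe = np.array(universe)
    middle = np.array(sorted(set(universe) - set(up) - set(down)))

    rng = np.random.default_rng(config.seed)
    names = ["reverser", "mimic"] + [
        f"decoy{i:03d}" for i in range(1, config.n_compounds - 1)
    ]

    profiles = []
    for name in names:
        for k in range(1, config.instances_per_compound + 1):
            if name == "reverser":
                ranking = _planted_ranking(rng, down, up, middle, config.reverser_noise)
            elif name == "mimic":
                ranking = _planted_ranking(rng, up, down, middle, config.reverser_noise)
            else:
                ranking = rng.permutation(universe)
            profiles.append(
                InstanceProfile(compound=name, instance_id=f"{name}_{k:02d}",
                                ranking=tuple(ranking))
            )
    return profiles


def _planted_ranking(rng, top, bottom, middle, noise) -> np.ndarray:
    """Ranking with ``top`` genes first and ``bottom`` genes last.

    With probability ``noise`` each signature gene is removed from its block
    and re-inserted at a uniformly random position.
    """
    ranking = np.concatenate([
        rng.permutation(np.array(top)) if len(top) else np.array([], dtype=object),
        rng.permutation(middle),
        rng.permutation(np.array(bottom)) if len(bottom) else np.array([], dtype=object),
    ])
    if noise > 0:
        ranking = list(ranking)
        for gene in list(top) + list(bottom):
            if rng.random() < noise:
                ranking.remove(gene)
                ranking.insert(int(rng.integers(0, len(ranking) + 1)), gene)
        ranking = np.array(ranking)
    return ranking


# -- gene sets --------------------------------------------------------------------

def generate_gene_sets(
    universe,
    n_sets: int = 20,
    size_range: tuple[int, int] = (10, 80),
    planted: dict[str, list] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene-set collection over ``universe``, plus optional planted sets."""
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    hi = min(hi, len(universe))
    lo = min(lo, hi)
    sets: dict[str, list[str]] = {}
    for name, genes in (planted or {}).items():
        sets[name] = list(genes)
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"RANDOM_SET_{i:03d}"] = sorted(str(g) for g in members)
    return sets


# -- fixture bundle ----------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, generated coherently from one seed."""

    table: ProteinQuantTable
    truth: GroundTruth
    ortholog_map: pd.DataFrame
    compound_db: list = field(default_factory=list)
    gene_sets: dict = field(default_factory=dict)


def write_fixtures(dataset: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Write every fixture to ``outdir``; returns the path of each artifact.

    All files round-trip losslessly through the readers in
    :mod:`proteoconnect.io`.
    """
    import os

    from . import io as pio

    pio.ensure_dir(outdir)
    paths = {
        "quant": os.path.join(outdir, "quant_table.tsv"),
        "orthologs": os.path.join(outdir, "ortholog_map.tsv"),
    }
    pio.write_quant_tsv(dataset.table, paths["quant"])
    pio.write_ortholog_tsv(dataset.ortholog_map, paths["orthologs"])
    if dataset.compound_db:
        paths["compound_db"] = os.path.join(outdir, "compound_db.tsv")
        pio.write_compound_db_tsv(dataset.compound_db, paths["compound_db"])
    if dataset.gene_sets:
        paths["gene_sets"] = os.path.join(outdir, "gene_sets.gmt")
        pio.write_gmt(dataset.gene_sets, paths["gene_sets"])
    return paths
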