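"""Configuration objects for the simulation and pipeline stages.

All stochastic stages take an explicit integer seed; every tunable that the
analysis leaves open (test variant, selection mode, counter-regulation filter
policy, percentile convention) is surfaced here with its default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


DEFAULT_GROUPS: tuple[str, ...] = ("WT", "DKD", "DKD+R", "WT+R")


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the synthetic 4-group glomerular proteome study.

    The study layout mirrors a label-free LC-MS/MS experiment on glomeruli
    from wild-type and diabetic (Akita) mice, each arm with and without the
    ACE inhibitor ramipril: groups WT, DKD, DKD+R, WT+R with 8 biological
    replicates each.  Intensities are generated on the log2 scale and stored
    on the raw scale (2**x), as MaxQuant-style protein tables are.

    Parameters
    ----------
    n_proteins
        Number of protein rows (the real study quantified ~2,400 proteins).
    groups, n_replicates
        Group labels (order matters: control, disease, disease+drug,
        control+drug) and biological replicates per group.
    baseline_log2_mean, baseline_log2_sd
        Location/scale of the per-protein baseline abundance on log2 scale.
    n_dkd_effect
        Number of proteins with a planted disease (DKD vs WT) effect.
    effect_log2_range
        (min, max) of the absolute planted log2 effect; signs are random.
    frac_rs
        Fraction of DKD-effect proteins counter-regulated by ramipril in the
        diabetic arm only (the drug-sensitive, disease-specific subset).
    frac_nonspecific
        Fraction of DKD-effect proteins whose ramipril response also occurs
        in non-diabetic mice (drug-sensitive but not disease-specific).
    rs_reversal_range
        Multiplicative factor range of the counter-regulation relative to the
        disease effect; 1.0 means exact cancellation.
    n_ramipril_only
        Proteins responding to ramipril (both treated arms) with no disease
        effect.
    noise_log2_sd
        Replicate-to-replicate noise, log2 scale.
    mnar_midpoint, mnar_slope
        Logistic missing-not-at-random model on the log2 scale:
        P(missing) = 1 / (1 + exp((x - midpoint)/slope)).  Defaults are
        calibrated so the mean missing fraction is ~2% under the default
        abundance model, matching the low missingness of a deep single-shot
        glomerular run.
    frac_contaminant
        Fraction of rows flagged as potential contaminants.  Contaminants get
        ordinary intensities — removing them is the preprocessing filter's
        job, not the simulator's.
    peptide_lambda
        Poisson mean of the per-protein peptide count (clipped to >= 1); a
        small tail of single-peptide identifications exercises the >= 2
        peptide filter.
    seed
        Seed for all randomness in the generator.
    """

    n_proteins: int = 2400
    groups: Sequence[str] = DEFAULT_GROUPS
    n_replicates: int = 8
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    n_dkd_effect: int = 600
    effect_log2_range: tuple[float, float] = (0.5, 2.5)
    frac_rs: float = 0.15
    frac_nonspecific: float = 0.05
    rs_reversal_range: tuple[float, float] = (0.8, 1.2)
    n_ramipril_only: int = 50
    noise_log2_sd: float = 0.5
    mnar_midpoint: float = 19.3
    mnar_slope: float = 1.0
    frac_contaminant: float = 0.02
    peptide_lambda: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_replicates <= 0:
            raise ConfigError("n_proteins and n_replicates must be positive")
        if len(self.groups) < 2:
            raise ConfigError("at least two groups are required")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("group labels must be unique")
        for name in ("frac_rs", "frac_nonspecific", "frac_contaminant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_rs + self.frac_nonspecific > 1.0:
            raise ConfigError("frac_rs + frac_nonspecific must be <= 1 for disjoint planting")
        if self.n_dkd_effect < 0 or self.n_ramipril_only < 0:
            raise ConfigError("planted effect counts must be non-negative")
        lo, hi = self.effect_log2_range
        if not (0 <= lo <= hi):
            raise ConfigError("effect_log2_range must satisfy 0 <= min <= max")
        if self.noise_log2_sd < 0 or self.baseline_log2_sd < 0:
            raise ConfigError("scale parameters must be non-negative")
        if self.mnar_slope <= 0:
            raise ConfigError("mnar_slope must be positive")


@dataclass(frozen=True)
class CompoundDbConfig:
    """Parameters of the synthetic compound-signature database.

    Emulates a connectivity-map compendium: per compound *instance* a full
    ranking of the gene universe by differential expression (rank 1 = most
    up-regulated).  One planted "reverser" ranks the query's down genes near
    the top and its up genes near the bottom; one planted "mimic" does the
    opposite; every other compound is a uniformly random decoy.
    """

    n_genes: int = 500
    n_compounds: int = 22
    instances_per_compound: int = 4
    reverser_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_compounds < 2:
            raise ConfigError("need at least the reverser and the mimic (n_compounds >= 2)")
        if self.instances_per_compound < 1:
            raise ConfigError("instances_per_compound must be >= 1")
        if not 0.0 <= self.reverser_noise <= 1.0:
            raise ConfigError("reverser_noise must lie in [0, 1]")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    ``input_table`` may be a path to a quant-table TSV or the literal string
    ``"simulate"``, in which case ``study`` drives the generator.
    """

    input_table: str = "simulate"
    study: StudyConfig = field(default_factory=StudyConfig)
    compound_db: CompoundDbConfig = field(default_factory=CompoundDbConfig)
    alpha: float = 0.05
    test: str = "welch"                 # "welch" | "student"
    selection_mode: str = "p"           # "p" (raw p) | "q" (BH q)
    filter2_policy: str = "same"        # "same" | "opposite" | "any"
    percentile: float = 1.0             # imputation percentile, percent units
    percentile_method: str = "linear"   # numpy percentile method
    min_obs: int = 4                    # quantification filter threshold
    n_perm: int = 1000
    n_null_queries: int = 100
    n_reference_queries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.test not in ("welch", "student"):
            raise ConfigError("test must be 'welch' or 'student'")
        if self.selection_mode not in ("p", "q"):
            raise ConfigError("selection_mode must be 'p' or 'q'")
        if self.filter2_policy not in ("same", "opposite", "any"):
            raise ConfigError("filter2_policy must be 'same', 'opposite' or 'any'")
        if not 0.0 <= self.percentile <= 100.0:
            raise ConfigError("percentile must lie in [0, 100]")
        if self.min_obs < 1:
            raise ConfigError("min_obs must be >= 1")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")


def load_pipeline_config(path: str) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "study" in raw and isinstance(raw["study"], dict):
        study = dict(raw["study"])
        for key in ("effect_log2_range", "rs_reversal_range"):
            if key in study:
                study[key] = tuple(study[key])
        if "groups" in study:
            study["groups"] = tuple(study["groups"])
        raw["study"] = StudyConfig(**study)
    if "compound_db" in raw and isinstance(raw["compound_db"], dict):
        raw["compound_db"] = CompoundDbConfig(**raw["compound_db"])
    return PipelineConfig(**raw)


def dump_pipeline_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
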