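"""Experiment configuration: nested dataclasses, YAML round-trip, and
deterministic fan-out of the master seed into per-stage seeds."""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import yaml

VALID_METHODS = ("BayesB", "G-BLUP", "P-BLUP")


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-stage seed: hashing the stage label means adding a
    scenario or trait never perturbs the draws of the others."""
    return zlib.crc32(f"{label}|{int(master_seed)}".encode()) % (2**31 - 1)


@dataclass
class PedigreeConfig:
    n_generations: int = 5
    founders_per_sex: int = 190
    sires_per_generation: int = 64
    offspring_per_sire: float = 6.0
    full_sib_rate: float = 0.08
    max_offspring_per_dam: int = 4
    family_size_skew: float = 0.35
    genotype_from_generation: int = 1  # males born in this generation onward are genotyped


@dataclass
class GenomeConfig:
    n_chromosomes: int = 5
    n_snps_per_chrom: int = 400
    chrom_length_bp: int = 25_600_000     # 0.064 Mb marker spacing, as in the LD reference
    n_reserve_per_chrom: int = 120        # hidden-QTL candidate sites
    effective_pop_size: float = 800.0
    recombination_rate: float = 1e-8      # 1 cM per Mb
    founder_model: str = "coalescent"     # or "independent" (linkage equilibrium)


@dataclass
class TraitConfig:
    name: str = "milk"
    h2: float = 0.53
    sigma2_a: float = 1.0
    n_qtl: int = 100
    effect_distribution: str = "gamma"    # few large QTL; "normal" for polygenic
    gamma_shape: float = 0.25


@dataclass
class QCConfig:
    max_missing_rate: float = 0.05
    min_maf: float = 0.03
    imputation: str = "mean_rounded"


@dataclass
class ScenarioConfig:
    a_max_grid: list = field(default_factory=lambda: [0.6, 0.249, 0.1249])
    reference_amax: float = 0.6
    train_sizes: list = field(default_factory=lambda: [400, 200])
    n_replicates: int = 20
    val_size: dict = field(default_factory=lambda: {0.6: 12, 0.249: 15, 0.1249: 12})
    min_val_size: dict = field(default_factory=lambda: {0.6: 8, 0.249: 10, 0.1249: 7})
    n_tries: int = 30
    protect_threshold: float = 0.25


@dataclass
class BayesBSettings:
    pi: float = 0.05
    nu_e: float = 4.2
    nu_beta: float = 4.2
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 4


@dataclass
class ExperimentConfig:
    seed: int = 1
    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    traits: list = field(default_factory=lambda: [TraitConfig()])
    qc: QCConfig = field(default_factory=QCConfig)
    scenarios: ScenarioConfig = field(default_factory=ScenarioConfig)
    bayesb: BayesBSettings = field(default_factory=BayesBSettings)
    methods: list = field(default_factory=lambda: list(VALID_METHODS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for m in self.methods:
            if m not in VALID_METHODS:
                raise ValueError(f"unknown method {m!r}; valid: {VALID_METHODS}")
        sc = self.scenarios
        if sc.reference_amax not in sc.a_max_grid:
            raise ValueError("reference_amax must be in the a_max grid")
        for a in sc.a_max_grid:
            if a not in sc.val_size or a not in sc.min_val_size:
                raise ValueError(f"a_max {a} lacks a validation-size entry")
        if sorted(self.train_sizes_desc(), reverse=True) != self.train_sizes_desc():
            raise ValueError("train_sizes must be given largest first")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names")

    def train_sizes_desc(self) -> list:
        return list(self.scenarios.train_sizes)

    def stage_seed(self, label: str) -> int:
        return derive_seed(self.seed, label)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        kw = {}
        nested = {
            "pedigree": PedigreeConfig,
            "genome": GenomeConfig,
            "qc": QCConfig,
            "scenarios": ScenarioConfig,
            "bayesb": BayesBSettings,
        }
        for key, typ in nested.items():
            if key in raw:
                kw[key] = typ(**raw.pop(key))
        if "traits" in raw:
            kw["traits"] = [TraitConfig(**t) for t in raw.pop("traits")]
        kw.update(raw)
        cfg = cls(**kw)
        # YAML represents the val-size mappings with float keys already
        cfg.scenarios.val_size = {float(k): int(v) for k, v in cfg.scenarios.val_size.items()}
        cfg.scenarios.min_val_size = {float(k): int(v) for k, v in cfg.scenarios.min_val_size.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
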