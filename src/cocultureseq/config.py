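"""Study-design configuration for the synthetic mixed-culture experiment.

The default configuration emulates a three-species fungal co-cultivation
design: glucose and wheat-straw monocultures for every species plus all
two-species and the three-species straw mixed cultures, three biological
replicates each, paired 2 x 75 bp reads. Sequencing depth is scaled to desk
size (the original design targeted ~30 M read pairs per monoculture and
~100 M per mixed-culture sample; the defaults here keep the 30:100 ratio at
1/1000 scale).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import yaml

GLUCOSE_MONO = "glucose_mono"
STRAW_MONO = "straw_mono"
MIXED_PREFIX = "mixed"


@dataclass
class EffectConfig:
    """Planted expression effects.

    straw_induction_fold
        Fold applied to straw-induced genes (a subset of the non-GT CAZy
        genes) in every straw-based condition relative to glucose.
    mixed_down_fold / mixed_up_fold
        Fold applied to the planted mixed-culture-responsive subsets in
        mixed cultures only.
    n_straw_induced, n_mixed_down, n_mixed_up
        Sizes of the planted subsets per species (capped at availability).
    """

    straw_induction_fold: float = 8.0
    mixed_down_fold: float = 4.0
    mixed_up_fold: float = 4.0
    n_straw_induced: int = 20
    n_mixed_down: int = 15
    n_mixed_up: int = 10

    def validate(self) -> None:
        for name in ("straw_induction_fold", "mixed_down_fold", "mixed_up_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class SimulationConfig:
    n_species: int = 3
    genome_length_bp: int = 100_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (300, 600)
    divergence: float = 0.10
    read_length: int = 75
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    depth_mono: int = 30_000
    depth_mixed: int = 100_000
    n_replicates: int = 3
    error_rate: float = 0.001
    lognormal_sigma: float = 1.5
    replicate_sigma: float = 0.05
    intergenic_fraction: float = 0.0
    cazy_fraction: float = 0.25
    rrna_copy_number: int = 50
    mixtures: list[tuple[int, ...]] | None = None
    effect_config: EffectConfig = field(default_factory=EffectConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.effect_config, dict):
            self.effect_config = EffectConfig(**self.effect_config)
        self.validate()

    def validate(self) -> None:
        if not (0 <= self.divergence < 1):
            raise ValueError(f"divergence must be in [0, 1), got {self.divergence}")
        if self.depth_mono <= 0 or self.depth_mixed <= 0:
            raise ValueError("sequencing depth must be > 0")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        self.effect_config.validate()

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def default_mixtures(self) -> list[tuple[int, ...]]:
        """All two-species pairs plus the full consortium."""
        idx = range(self.n_species)
        pairs = [p for p in itertools.combinations(idx, 2)]
        full = [tuple(idx)] if self.n_species > 2 else []
        return pairs + full

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mixtures" in raw and raw["mixtures"] is not None:
            raw["mixtures"] = [tuple(m) for m in raw["mixtures"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing library: condition, replicate, mixture and depth."""

    sample_id: str
    condition: str
    replicate: int
    proportions: dict[str, float]
    depth: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix proportions must sum to 1, got {total}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


def mixture_condition(species_ids: list[str]) -> str:
    return MIXED_PREFIX + "_" + "_".join(species_ids)


def build_sample_sheet(cfg: SimulationConfig) -> list[SampleSpec]:
    """Enumerate all libraries of the configured design.

    Monocultures on glucose and straw for every species, then every
    configured straw mixed culture with equal inoculation proportions.
    """
    species = cfg.species_ids
    samples: list[SampleSpec] = []
    for sp in species:
        for cond in (GLUCOSE_MONO, STRAW_MONO):
            for rep in range(1, cfg.n_replicates + 1):
                samples.append(
                    SampleSpec(
                        sample_id=f"{sp}_{cond}_r{rep}",
                        condition=f"{sp}:{cond}",
                        replicate=rep,
                        proportions={sp: 1.0},
                        depth=cfg.depth_mono,
                    )
                )
    mixtures = cfg.mixtures if cfg.mixtures is not None else cfg.default_mixtures()
    for mix in mixtures:
        members = [species[i] for i in mix]
        cond = mixture_condition(members)
        share = 1.0 / len(members)
        for rep in range(1, cfg.n_replicates + 1):
            samples.append(
                SampleSpec(
                    sample_id=f"{cond}_r{rep}",
                    condition=cond,
                    replicate=rep,
                    proportions={m: share for m in members},
                    depth=cfg.depth_mixed,
                )
            )
    return samples


def is_straw_condition(condition: str) -> bool:
    return condition.endswith(STRAW_MONO) or condition.startswith(MIXED_PREFIX)


def is_mixed_condition(condition: str) -> bool:
    return condition.startswith(MIXED_PREFIX)
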