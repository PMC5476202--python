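"""Condition-dependent true expression with planted effects.

Baseline transcript abundance per gene is heavy-tailed (log-normal); straw
conditions induce a planted subset of the non-GT CAZy genes, and mixed
cultures down- or up-regulate further planted subsets. Per-replicate
log-normal jitter models biological replication. Expected transcript
fractions are renormalised to sum to one per species-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig, is_mixed_condition, is_straw_condition
from .genomes import SpeciesGenome

ENVS = ("glucose", "straw", "mixed")

LABEL_NONE = "none"
LABEL_STRAW = "straw-induced"
LABEL_MIXED_DOWN = "mixed-down"
LABEL_MIXED_UP = "mixed-up"


def env_of(condition: str) -> str:
    """Map a sample condition label to its expression environment."""
    if is_mixed_condition(condition):
        return "mixed"
    return "straw" if is_straw_condition(condition) else "glucose"


@dataclass
class TrueExpression:
    """Expected transcript fractions per (species, env, replicate)."""

    gene_ids: dict[str, list[str]]
    fractions: dict[tuple[str, str, int], np.ndarray]
    labels: dict[str, dict[str, str]] = field(default_factory=dict)

    def fraction_for(self, species: str, condition: str, replicate: int) -> np.ndarray:
        return self.fractions[(species, env_of(condition), replicate)]

    def genes_with_label(self, species: str, label: str) -> list[str]:
        return [g for g, lab in self.labels[species].items() if lab == label]


def simulate_expression(
    cfg: SimulationConfig,
    genomes: list[SpeciesGenome],
    seed: int | None = None,
) -> TrueExpression:
    if seed is None:
        seed = cfg.seed + 1
    rng = np.random.default_rng(seed)
    eff = cfg.effect_config
    eff.validate()

    gene_ids: dict[str, list[str]] = {}
    fractions: dict[tuple[str, str, int], np.ndarray] = {}
    labels: dict[str, dict[str, str]] = {}

    for genome in genomes:
        sp = genome.species_id
        gids = [g.gene_id for g in genome.gene_models]
        gene_ids[sp] = gids
        n = len(gids)
        base = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=n)

        cazy_non_gt = [
            i for i, g in enumerate(gids)
            if (fam := genome.annotations.get(g, {}).get("cazy")) and not fam.startswith("GT")
        ]
        others = [i for i in range(n) if i not in set(cazy_non_gt)]
        rng.shuffle(cazy_non_gt)
        # mixed-culture-reduced genes are straw-induced CAZy genes that lose
        # (part of) their induction in co-culture, mirroring the biology of
        # major straw-degrading CAZymes
        straw_idx = cazy_non_gt[: eff.n_straw_induced]
        down_idx = straw_idx[: eff.n_mixed_down]
        up_pool = list(others)
        rng.shuffle(up_pool)
        up_idx = up_pool[: eff.n_mixed_up]

        lab = {g: LABEL_NONE for g in gids}
        for i in straw_idx:
            lab[gids[i]] = LABEL_STRAW
        for i in down_idx:
            lab[gids[i]] = LABEL_MIXED_DOWN
        for i in up_idx:
            lab[gids[i]] = LABEL_MIXED_UP
        labels[sp] = lab

        straw_mask = np.zeros(n)
        straw_mask[straw_idx] = 1.0
        down_mask = np.zeros(n)
        down_mask[down_idx] = 1.0
        up_mask = np.zeros(n)
        up_mask[up_idx] = 1.0

        for env in ENVS:
            w = base.copy()
            if env in ("straw", "mixed"):
                w *= np.where(straw_mask > 0, eff.straw_induction_fold, 1.0)
            if env == "mixed":
                w /= np.where(down_mask > 0, eff.mixed_down_fold, 1.0)
                w *= np.where(up_mask > 0, eff.mixed_up_fold, 1.0)
            for rep in range(1, cfg.n_replicates + 1):
                noisy = w * rng.lognormal(0.0, cfg.replicate_sigma, size=n) if cfg.replicate_sigma > 0 else w
                fractions[(sp, env, rep)] = noisy / noisy.sum()

    return TrueExpression(gene_ids=gene_ids, fractions=fractions, labels=labels)
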