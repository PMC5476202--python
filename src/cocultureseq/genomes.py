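"""Synthetic multi-species genome generation.

Genomes are generated from one ancestral sequence so that coordinates are
directly comparable across species: divergence is substitution-only, applied
at disjoint per-species position sets of size L*d/2 drawn from a common
pool, which makes every pairwise divergence exactly ``d``. Each genome
carries intronless gene models, a multi-copy rRNA-like marker locus with
species-discriminating sites, a single-copy locus for gDNA-based biomass
work, and CAZy-family / term annotations for a configurable fraction of
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# marker layout inside the reserved head of the contig (0-based, half-open)
_RRNA_SPAN = (100, 400)
_SINGLE_COPY_SPAN = (500, 700)
_RESERVED_BP = 1000

CAZY_FAMILIES = ("GH5", "GH7", "GH10", "GH11", "CE1", "CE5", "PL1", "AA9")
GT_FAMILIES = ("GT2", "GT4")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted, disjoint

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end or end < start:
                raise ValueError(f"{self.gene_id}: exons must be sorted and disjoint")
            prev_end = end
        if self.length < 1:
            raise ValueError(f"{self.gene_id}: empty gene model")

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class MarkerLocus:
    locus_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    copy_number: int
    discriminating_positions: tuple[int, ...] = ()  # offsets within the locus


@dataclass
class SpeciesGenome:
    species_id: str
    contigs: dict[str, str]
    gene_models: list[GeneModel]
    marker_rrna: MarkerLocus
    marker_single_copy: MarkerLocus
    annotations: dict[str, dict] = field(default_factory=dict)

    def contig_length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene_index()[gene_id]

    def _gene_index(self) -> dict[str, GeneModel]:
        if not hasattr(self, "_genes_by_id"):
            self._genes_by_id = {g.gene_id: g for g in self.gene_models}
        return self._genes_by_id

    def transcript_sequence(self, gene: GeneModel) -> str:
        seq = self.contigs[gene.contig]
        spliced = "".join(seq[s - 1 : e] for s, e in gene.exons)
        if gene.strand == "-":
            spliced = reverse_complement(spliced)
        return spliced


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _place_genes(rng: np.random.Generator, cfg: SimulationConfig) -> list[tuple[int, int]]:
    """Non-overlapping 1-based gene intervals downstream of the marker head."""
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    usable = cfg.genome_length_bp - _RESERVED_BP
    slack = usable - int(lengths.sum()) - cfg.n_genes  # >=1 bp gap between genes
    if slack < 0:
        raise ValueError(
            f"genome of {cfg.genome_length_bp} bp cannot host {cfg.n_genes} genes "
            f"(need >= {_RESERVED_BP + int(lengths.sum()) + cfg.n_genes} bp)"
        )
    # distribute the remaining slack over the n_genes+1 gaps
    gaps = rng.multinomial(slack, np.full(cfg.n_genes + 1, 1.0 / (cfg.n_genes + 1)))
    intervals = []
    pos = _RESERVED_BP + 1  # first available 1-based coordinate
    for i, L in enumerate(lengths):
        pos += int(gaps[i]) + 1
        intervals.append((pos, pos + int(L) - 1))
        pos += int(L)
    return intervals


def _annotate(rng: np.random.Generator, gene_ids: list[str], cfg: SimulationConfig) -> dict[str, dict]:
    n = len(gene_ids)
    n_cazy = max(1, int(round(cfg.cazy_fraction * n)))
    cazy_idx = rng.choice(n, size=n_cazy, replace=False)
    n_gt = max(1, n_cazy // 6)
    families = {}
    for j, gi in enumerate(cazy_idx):
        pool = GT_FAMILIES if j < n_gt else CAZY_FAMILIES
        families[gene_ids[gi]] = pool[j % len(pool)]
    transport = set(rng.choice(n, size=max(1, n // 10), replace=False))
    ann = {}
    for i, gid in enumerate(gene_ids):
        fam = families.get(gid)
        terms = []
        if fam is not None:
            terms.append("glycosyl_transfer" if fam.startswith("GT") else "polysaccharide_degradation")
        if i in transport:
            terms.append("membrane_transport")
        ann[gid] = {"cazy": fam, "terms": terms}
    return ann


def generate_genomes(cfg: SimulationConfig) -> list[SpeciesGenome]:
    """Generate one genome per species, deterministic for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length_bp
    if L < _RESERVED_BP + cfg.gene_length_range[1]:
        raise ValueError(
            f"genome_length_bp={L} too small (need >= {_RESERVED_BP + cfg.gene_length_range[1]})"
        )
    ancestral = rng.integers(0, 4, size=L, dtype=np.uint8)
    intervals = _place_genes(rng, cfg)
    strands = rng.choice(np.array(["+", "-"]), size=cfg.n_genes)

    n_sub = int(round(L * cfg.divergence / 2.0))
    forced = []
    if cfg.divergence > 0:
        base_off = (_RRNA_SPAN[0] + _RRNA_SPAN[1]) // 2
        forced = [base_off + i for i in range(cfg.n_species)]
    pool = np.setdiff1d(np.arange(L), np.array(forced, dtype=int), assume_unique=False)
    need = n_sub * cfg.n_species
    if need > pool.size:
        raise ValueError("divergence too high for disjoint substitution sets")
    chosen = rng.choice(pool, size=need, replace=False) if need else np.empty(0, dtype=int)

    genomes = []
    for s in range(cfg.n_species):
        sp = cfg.species_ids[s]
        seq = ancestral.copy()
        sites = chosen[s * n_sub : (s + 1) * n_sub]
        if sites.size:
            shift = rng.integers(1, 4, size=sites.size).astype(np.uint8)
            seq[sites] = (seq[sites] + shift) % 4
        if forced:
            pos = forced[s]
            seq[pos] = (ancestral[pos] + 1 + s) % 4
        contig_seq = BASES[seq].tobytes().decode()

        gene_ids = [f"{sp}_g{i + 1:04d}" for i in range(cfg.n_genes)]
        models = [
            GeneModel(gene_id=gid, contig="chr1", strand=strands[i], exons=((a, b),))
            for i, (gid, (a, b)) in enumerate(zip(gene_ids, intervals))
        ]
        rrna = MarkerLocus(
            locus_id=f"{sp}_rrna",
            contig="chr1",
            start=_RRNA_SPAN[0] + 1,
            end=_RRNA_SPAN[1],
            copy_number=cfg.rrna_copy_number,
            discriminating_positions=tuple(p - _RRNA_SPAN[0] for p in forced),
        )
        single = MarkerLocus(
            locus_id=f"{sp}_single_copy",
            contig="chr1",
            start=_SINGLE_COPY_SPAN[0] + 1,
            end=_SINGLE_COPY_SPAN[1],
            copy_number=1,
        )
        ann_rng = np.random.default_rng(cfg.seed + 10_000 + s)
        genomes.append(
            SpeciesGenome(
                species_id=sp,
                contigs={"chr1": contig_seq},
                gene_models=models,
                marker_rrna=rrna,
                marker_single_copy=single,
                annotations=_annotate(ann_rng, gene_ids, cfg),
            )
        )
    return genomes


def pairwise_divergence(a: SpeciesGenome, b: SpeciesGenome, contig: str = "chr1") -> float:
    """Observed mismatch fraction between two equal-length contigs."""
    x = np.frombuffer(a.contigs[contig].encode(), dtype=np.uint8)
    y = np.frombuffer(b.contigs[contig].encode(), dtype=np.uint8)
    if x.size != y.size:
        raise ValueError("contigs differ in length")
    return float((x != y).mean())
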