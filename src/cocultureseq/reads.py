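"""Paired-end read simulation with exact per-fragment truth.

Each fragment picks a species from the sample's mixture proportions, a gene
from that species' expected transcript fractions, a length from a clipped
normal, and a uniform position within the spliced transcript. The library is
directional (dUTP-style): read 2 carries the transcript sense, read 1 its
reverse complement. Substitution errors are applied at a fixed per-base
rate; qualities are constant (Q30).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SampleSpec, SimulationConfig
from .expression import TrueExpression
from .genomes import GeneModel, SpeciesGenome, reverse_complement

INTERGENIC = "intergenic"
QUALITY_CHAR = "?"  # Phred+33 Q30

_BASES = "ACGT"


@dataclass
class ReadPairs:
    sample_id: str
    ids: list[str]
    r1: list[str]
    r2: list[str]
    truth: pd.DataFrame  # fragment_id, species, gene_id, contig, start, end, strand
    n_resampled: int = 0

    def __len__(self) -> int:
        return len(self.ids)


def _transcript_to_genomic(gene: GeneModel, t0: int, t1: int) -> tuple[int, int]:
    """Map an inclusive transcript interval to its genomic span (1-based)."""
    length = gene.length
    if gene.strand == "-":
        t0, t1 = length - 1 - t1, length - 1 - t0
    coords = []
    for t in (t0, t1):
        off = t
        for start, end in gene.exons:
            exon_len = end - start + 1
            if off < exon_len:
                coords.append(start + off)
                break
            off -= exon_len
    return coords[0], coords[1]


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in pos:
        old = chars[p]
        chars[p] = _BASES[(_BASES.index(old) + rng.integers(1, 4)) % 4]
    return "".join(chars)


def simulate_read_pairs(
    cfg: SimulationConfig,
    genomes: list[SpeciesGenome],
    expr: TrueExpression,
    sample: SampleSpec,
    seed: int | None = None,
) -> ReadPairs:
    if seed is None:
        seed = cfg.seed + 100 + zlib.crc32(sample.sample_id.encode()) % 2**20
    rng = np.random.default_rng(seed)
    rl = cfg.read_length
    by_id = {g.species_id: g for g in genomes}
    species = sorted(sample.proportions)
    props = np.array([sample.proportions[s] for s in species])
    n_per_species = rng.multinomial(sample.depth, props)

    ids: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    rows = []
    n_resampled = 0
    frag_no = 0

    for sp, n_sp in zip(species, n_per_species):
        if n_sp == 0:
            continue
        genome = by_id[sp]
        fracs = expr.fraction_for(sp, sample.condition, sample.replicate)
        n_intergenic = rng.binomial(n_sp, cfg.intergenic_fraction) if cfg.intergenic_fraction > 0 else 0
        n_genic = n_sp - n_intergenic
        gene_counts = rng.multinomial(n_genic, fracs)
        transcripts = {}
        jobs: list[tuple[GeneModel | None, int]] = [
            (genome.gene_models[gi], int(c)) for gi, c in enumerate(gene_counts) if c > 0
        ]
        if n_intergenic:
            jobs.append((None, n_intergenic))
        for gene, count in jobs:
            if gene is not None:
                tseq = transcripts.setdefault(gene.gene_id, genome.transcript_sequence(gene))
                tlen = len(tseq)
            else:
                contig = next(iter(genome.contigs))
                tseq = genome.contigs[contig]
                tlen = len(tseq)
            for _ in range(count):
                fl = int(round(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd)))
                fl = max(fl, rl)
                if fl > tlen:
                    for _ in range(5):
                        fl = max(int(round(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd))), rl)
                        if fl <= tlen:
                            break
                    else:
                        fl = tlen
                    n_resampled += 1
                t0 = int(rng.integers(0, tlen - fl + 1))
                frag = tseq[t0 : t0 + fl]
                mate2 = _apply_errors(frag[:rl], rng, cfg.error_rate)
                mate1 = _apply_errors(reverse_complement(frag[fl - rl :]), rng, cfg.error_rate)
                frag_no += 1
                fid = f"{sample.sample_id}:f{frag_no:07d}"
                ids.append(fid)
                r1.append(mate1)
                r2.append(mate2)
                if gene is not None:
                    gstart, gend = _transcript_to_genomic(gene, t0, t0 + fl - 1)
                    if gene.strand == "-":
                        gstart, gend = min(gstart, gend), max(gstart, gend)
                    rows.append((fid, sp, gene.gene_id, gene.contig, gstart, gend, gene.strand))
                else:
                    rows.append((fid, sp, INTERGENIC, contig, t0 + 1, t0 + fl, "+"))

    if n_resampled:
        warnings.warn(f"{n_resampled} fragments exceeded their transcript and were resampled/truncated")
    truth = pd.DataFrame(
        rows, columns=["fragment_id", "species", "gene_id", "contig", "start", "end", "strand"]
    )
    return ReadPairs(sample.sample_id, ids, r1, r2, truth, n_resampled)


def write_fastq_pair(reads: ReadPairs, path1, path2) -> None:
    for path, seqs in ((path1, reads.r1), (path2, reads.r2)):
        with open(path, "w") as fh:
            for fid, seq in zip(reads.ids, seqs):
                fh.write(f"@{fid}\n{seq}\n+\n{QUALITY_CHAR * len(seq)}\n")
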