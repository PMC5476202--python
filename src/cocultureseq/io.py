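"""Readers and writers for the standard formats the pipeline touches."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomes import GeneModel, SpeciesGenome


def write_fasta(genome: SpeciesGenome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig, description=genome.species_id)
        for contig, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_composite_fasta(genomes: list[SpeciesGenome], path) -> None:
    """Concatenated reference with species-tagged contig names."""
    records = [
        SeqRecord(Seq(seq), id=f"{g.species_id}|{contig}", description="")
        for g in genomes
        for contig, seq in g.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genome: SpeciesGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.gene_models:
            span = g.span
            fh.write(
                f"{g.contig}\tcocultureseq\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\tcocultureseq\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id};gene_id={g.gene_id}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Gene models from a GFF3 with exon rows carrying a gene_id attribute."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start, gene.end)]
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        models.append(GeneModel(gene_id=gid, contig=gene.seqid, strand=gene.strand,
                                exons=tuple(exons)))
    return models


def read_fastq(path) -> tuple[list[str], list[str]]:
    ids, seqs = [], []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            ids.append(rec.name)
            seqs.append(rec.sequence)
    return ids, seqs


def read_fastq_pair(path1, path2) -> tuple[list[str], list[str], list[str]]:
    ids1, r1 = read_fastq(path1)
    ids2, r2 = read_fastq(path2)
    if ids1 != ids2:
        raise ValueError("mate files disagree on read ids/order")
    return ids1, r1, r2


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
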