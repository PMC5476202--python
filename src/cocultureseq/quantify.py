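"""Species-specific FPKM and annotation-set aggregates.

FPKM here is computed per species against that species' own uniquely
assigned fragment total: FPKM_gs = C_gs * 1e9 / (L_g * M_s), where M_s is
the number of uniquely assigned fragments counted onto that species' gene
models in sample s (never the whole-sample total). This makes the identity
sum_g FPKM_gs * L_g/1e3 = 1e6 hold exactly for every species-sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomes import GeneModel

DEFAULT_INCLUDE_CLASSES = ("GH", "CE", "PL", "AA")
DEFAULT_EXCLUDE_CLASSES = ("GT",)


@dataclass
class ExpressionMatrix:
    species_id: str
    fpkm: pd.DataFrame  # genes x samples
    gene_lengths: pd.Series  # bp per gene
    library_sizes: pd.Series  # M_s per sample (gene-model-counted fragments)
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.fpkm.fillna(0) < 0).any().any():
            raise ValueError("FPKM must be non-negative")


def compute_fpkm(
    counts: pd.DataFrame,
    gene_models: list[GeneModel] | pd.Series,
    species_id: str = "",
    library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """FPKM from a gene x sample count matrix.

    ``library_sizes`` defaults to the column sums of ``counts`` (i.e. all
    counted-in-genes fragments); pass explicit M_s values to override.
    Samples with M_s = 0 yield an all-missing column with a warning.
    """
    if isinstance(gene_models, pd.Series):
        lengths = gene_models.astype(float)
    else:
        lengths = pd.Series({g.gene_id: float(g.length) for g in gene_models})
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no gene length for: {list(missing)[:5]}")
    lengths = lengths.reindex(counts.index)
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")

    if library_sizes is None:
        m = counts.sum(axis=0).astype(float)
    else:
        m = library_sizes.reindex(counts.columns).astype(float)
    fpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(m, axis=1)
    zero = m[m <= 0].index
    if len(zero):
        warnings.warn(f"samples with zero counted fragments: {list(zero)}")
        fpkm[zero] = np.nan
    return ExpressionMatrix(species_id, fpkm, lengths, m, counts=counts)


@dataclass
class AggregateSeries:
    totals: pd.Series  # per-sample total FPKM over the gene set
    genes: list[str]
    summary: pd.DataFrame | None = None  # per-group mean and standard error


def cazy_class(family: str | None) -> str | None:
    """CAZy class prefix of a family name, e.g. 'GH7' -> 'GH'."""
    if not family:
        return None
    return "".join(ch for ch in family if ch.isalpha())


def aggregate_set_fpkm(
    fpkm: pd.DataFrame,
    annotations: dict[str, dict],
    include_classes=DEFAULT_INCLUDE_CLASSES,
    exclude_classes=DEFAULT_EXCLUDE_CLASSES,
    sample_groups: dict[str, list[str]] | None = None,
) -> AggregateSeries:
    """Total FPKM over an annotation-defined gene set.

    Default selection is the degradative CAZy classes (GH, CE, PL, AA) with
    glycosyltransferases (GT) excluded, since GTs do not act on plant
    biomass. ``sample_groups`` (group -> sample columns) adds a replicate
    mean +- standard error summary per group.
    """
    genes = []
    for gid in fpkm.index:
        cls = cazy_class(annotations.get(gid, {}).get("cazy"))
        if cls is None:
            continue
        if cls in include_classes and cls not in exclude_classes:
            genes.append(gid)
    if not genes:
        warnings.warn("no genes matched the annotation filter; totals are 0")
        totals = pd.Series(0.0, index=fpkm.columns)
    else:
        totals = fpkm.loc[genes].sum(axis=0)
    summary = None
    if sample_groups:
        rows = {}
        for group, cols in sample_groups.items():
            mean, se = replicate_summary(totals[cols].to_numpy())
            rows[group] = {"mean": mean, "se": se, "n": len(cols)}
        summary = pd.DataFrame(rows).T
    return AggregateSeries(totals=totals, genes=genes, summary=summary)


def replicate_summary(values) -> tuple[float, float]:
    """Replicate mean and standard error (sample sd / sqrt(n)); needs n >= 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need >= 2 replicates, got {v.size}")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
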