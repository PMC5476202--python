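"""End-to-end synthetic study: simulate, assign, count, quantify, test.

``run_study`` executes the whole desk-scale experiment for a configuration:
genome generation, condition-dependent expression, read simulation per
library, composite-reference species assignment, per-species fragment
counting and FPKM. The result object then supports the downstream analyses
(differential expression between conditions, CAZy-set aggregation,
marker-based read-share validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assign import KmerSpeciesClassifier, assignment_confusion, count_fragments
from .config import SampleSpec, SimulationConfig, build_sample_sheet
from .diffexpr import DEResult, NegativeBinomialWaldDE
from .expression import TrueExpression, simulate_expression
from .genomes import SpeciesGenome, generate_genomes
from .quantify import ExpressionMatrix, aggregate_set_fpkm, compute_fpkm
from .reads import simulate_read_pairs


@dataclass
class StudyResult:
    cfg: SimulationConfig
    genomes: list[SpeciesGenome]
    expression: TrueExpression
    samples: list[SampleSpec]
    counts: dict[str, pd.DataFrame]  # species -> genes x samples
    library_sizes: dict[str, pd.Series]  # species -> M_s per sample
    unique_totals: pd.DataFrame  # species x samples uniquely assigned fragments
    fpkm: dict[str, ExpressionMatrix]
    confusion_rates: pd.DataFrame  # per-sample assignment summary
    classifier: KmerSpeciesClassifier | None = None
    labels: dict[str, dict[str, str]] = field(default_factory=dict)

    def samples_for(self, species: str, condition: str) -> list[str]:
        return [
            s.sample_id for s in self.samples
            if s.condition == condition and s.proportions.get(species, 0) > 0
        ]

    def de(self, species: str, test_condition: str, control_condition: str,
           **params) -> DEResult:
        """NB Wald DE of a species between two conditions, with the call rule."""
        test_cols = self.samples_for(species, test_condition)
        ctrl_cols = self.samples_for(species, control_condition)
        cols = ctrl_cols + test_cols
        counts = self.counts[species][cols]
        groups = pd.Series(["control"] * len(ctrl_cols) + ["test"] * len(test_cols), index=cols)
        model = NegativeBinomialWaldDE(**params).fit(counts, groups)
        return model.call(self.fpkm[species].fpkm, test_label="test")

    def aggregate_cazy(self, species: str, **kwargs):
        genome = next(g for g in self.genomes if g.species_id == species)
        return aggregate_set_fpkm(self.fpkm[species].fpkm, genome.annotations, **kwargs)

    def realized_read_share(self, sample_id: str) -> dict[str, float]:
        """Fraction of the sample's uniquely assigned fragments per species."""
        col = self.unique_totals[sample_id]
        total = col.sum()
        return (col / total).to_dict() if total > 0 else {sp: np.nan for sp in col.index}


def run_study(
    cfg: SimulationConfig,
    samples: list[SampleSpec] | None = None,
    classifier: KmerSpeciesClassifier | None = None,
    stranded_mode: str = "reverse",
) -> StudyResult:
    genomes = generate_genomes(cfg)
    expr = simulate_expression(cfg, genomes)
    if samples is None:
        samples = build_sample_sheet(cfg)
    if classifier is None:
        classifier = KmerSpeciesClassifier().fit(genomes)
    gene_models = {g.species_id: g.gene_models for g in genomes}
    species_ids = [g.species_id for g in genomes]

    count_cols: dict[str, dict[str, pd.Series]] = {sp: {} for sp in species_ids}
    m_s: dict[str, dict[str, float]] = {sp: {} for sp in species_ids}
    unique_tot = pd.DataFrame(0, index=species_ids, columns=[s.sample_id for s in samples])
    conf_rows = {}

    for sample in samples:
        reads = simulate_read_pairs(cfg, genomes, expr, sample)
        asg = classifier.assign(reads.r1, reads.r2, ids=reads.ids)
        fc = count_fragments(asg, gene_models, stranded_mode=stranded_mode)
        conf = assignment_confusion(reads.truth, asg)
        conf_rows[sample.sample_id] = conf["rates"]
        for sp in species_ids:
            unique_tot.loc[sp, sample.sample_id] = fc.unique_total[sp]
            if sample.proportions.get(sp, 0) > 0:
                count_cols[sp][sample.sample_id] = fc.counts[sp]
                m_s[sp][sample.sample_id] = fc.counted_total[sp]

    counts = {}
    fpkm = {}
    library_sizes = {}
    for sp in species_ids:
        if not count_cols[sp]:
            continue
        mat = pd.DataFrame(count_cols[sp])
        sizes = pd.Series(m_s[sp])
        counts[sp] = mat
        library_sizes[sp] = sizes
        fpkm[sp] = compute_fpkm(mat, gene_models[sp], species_id=sp, library_sizes=sizes)

    return StudyResult(
        cfg=cfg,
        genomes=genomes,
        expression=expr,
        samples=samples,
        counts=counts,
        library_sizes=library_sizes,
        unique_totals=unique_tot,
        fpkm=fpkm,
        confusion_rates=pd.DataFrame(conf_rows).T,
        classifier=classifier,
        labels=expr.labels,
    )
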