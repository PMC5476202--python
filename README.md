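# cocultureseq

Dual RNA-seq quantification for fungal mixed cultures, as a tested, reusable
pipeline on synthetic data.

When several fungi (e.g. *Trichoderma reesei*, *Aspergillus niger*,
*Penicillium chrysogenum*) grow together on a lignocellulosic substrate and
their pooled RNA is sequenced, every analysis step has to attribute reads to
species before anything can be quantified. This package implements that
workflow end to end:

- **Composite-reference species assignment.** All genomes are concatenated
  into one species-tagged reference; each read pair is counted by exact
  k-mer hits per species over both mates and strands and assigned uniquely
  only when the best species dominates (second-best/best hit ratio below a
  margin; any tie is ambiguous and the pair is discarded). The fragment
  locus is inferred from the modal alignment diagonal of species-exclusive
  k-mers.
- **Per-species FPKM.** For gene *g* of species *s* in sample *j*:
  `FPKM_gj = C_gj * 1e9 / (L_g * M_sj)`, where `C_gj` are uniquely assigned
  fragments counted onto the gene model, `L_g` the summed exon length in bp
  and `M_sj` that species' own gene-model-counted fragment total — never the
  whole-sample total. The identity `sum_g FPKM_gj * L_g/1e3 = 1e6` holds
  exactly per species-sample.
- **Differential expression.** Median-of-ratios size factors, a
  negative-binomial Wald test with trend-moderated method-of-moments
  dispersions, Benjamini–Hochberg adjustment, and the study's call rule:
  fold change ≥ 2 on normalised counts, `p_adj < 0.05`, and FPKM ≥ 1 in the
  test (up) or control (down) condition.
- **CAZy aggregation and clustering.** Total CAZyme FPKM over the
  degradative classes (GH/CE/PL/AA, glycosyltransferases excluded),
  replicate mean ± SE; gene selection, `log2(x+1)` transform,
  uncentered-correlation distance `d = 1 − Σxy/√(Σx²Σy²)` and
  complete-linkage clustering; hypergeometric term enrichment of DE lists.
- **qPCR marker quantification.** Log-linear standard curves
  (`Ct = b + m·log10(copies)`, efficiency `E = 10^(−1/m) − 1`) fitted on
  ten five-fold plasmid dilutions from 5×10⁷ copies; species-specific
  5.8S-rRNA-style marker copies → mixture shares → predicted read yield;
  single-copy-locus gDNA against 2–50 mg dry-weight standards → biomass per
  species, scaled from the extraction aliquot to the whole flask.
- **Assay arithmetic.** pNP activities in ρmol·min⁻¹·μl⁻¹, DNS
  reducing-sugar release corrected for straw and filtrate backgrounds, and
  per-biomass normalisation.
- **Synthetic data generator.** First-class, tested code that emulates the
  study design: three ~100 kb genomes diverged from one ancestor
  (substitution-only, so coordinates stay comparable), intronless gene
  models, planted straw-induction and mixed-culture effects, paired 2×75 bp
  directional reads with exact per-fragment truth, qPCR plates and gDNA
  biomass samples.

## Worked example

```python
import cocultureseq as cq
from cocultureseq.config import mixture_condition

cfg = cq.SimulationConfig(depth_mono=50_000, depth_mixed=50_000,
                          mixtures=[(0, 1, 2)], seed=1)
res = cq.run_study(cfg)

print(res.confusion_rates[["unique_correct_fraction", "misassignment_rate"]].mean())
# unique_correct_fraction    0.997562
# misassignment_rate         0.000000

mix = mixture_condition(["sp1", "sp2", "sp3"])
de = res.de("sp1", test_condition=mix, control_condition="sp1:straw_mono")
planted = set(res.expression.genes_with_label("sp1", "mixed-down"))
print(len(de.down_genes), len(planted & set(de.down_genes)))
# 15 15
```

The first block runs the full tri-species study (21 libraries of 50,000 read
pairs each): 99.8% of pairs are uniquely and correctly assigned at 10%
divergence and none to a wrong species. The DE call (fold ≥ 2,
`p_adj` < 0.05, FPKM ≥ 1) then recovers exactly the 15 planted
mixed-culture-reduced CAZy genes of species `sp1`.

A command-line interface mirrors the library
(`cocultureseq simulate|run|assign|fpkm|de|cluster|enrich|markers|assays`).

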