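# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `cocultureseq`. The package quantifies multi-species
("dual") RNA-seq from fungal mixed cultures and the companion qPCR
measurements, and ships a synthetic-data generator that emulates the
corresponding study design so that every stage can be validated against
planted truth.

## The synthetic study

The generator emulates a three-species co-cultivation experiment: each
fungus grown on glucose and on wheat straw as monocultures, plus straw
mixed cultures (all two-species pairs and the trio by default), three
biological replicates per condition, paired 2×75 bp directional reads.
Sequencing depth defaults to 30,000 read pairs per monoculture and 100,000
per mixed-culture library — a 1/1000 scale model of the ~30 M / ~100 M
design it emulates, keeping the mono:mixed ratio. Analyses in the test
suite and acceptance script use 50,000 pairs per library with the trio
mixture only, 200 genes per 100 kb genome; these sizes are the package's
desk-scale study conditions.

**Genomes.** One random ancestral sequence per study; each species receives
substitutions at a disjoint set of `L·d/2` positions drawn from a common
pool, so every pairwise divergence is exactly `d` (default 0.10,
substitution-only — no indels — so coordinates stay comparable across
species and the uniqueness-vs-divergence question is isolated). Gene models
are intronless (single exon, 300–600 bp by default), placed without
overlap downstream of a reserved marker head; a ~300 bp multi-copy
rRNA-like marker (50 copies/genome by default, with one forced
species-specific substitution per species when `d > 0`) and a single-copy
locus occupy the head. A configurable fraction of genes (default 0.25)
receives CAZy families spanning GH/CE/PL/AA plus GT, and flat term labels
for enrichment.

**Expression.** Baselines are log-normal (σ = 1.5) per gene, giving the
heavy-tailed abundance distribution of real RNA-seq. Planted effects:
a straw-induced subset of the non-GT CAZy genes (default 20/species,
fold 8 in every straw-based condition), of which a subset (default
15/species, the "mixed-down" genes) loses a 4-fold factor in mixed
cultures — mirroring the biology where the genes reduced in co-culture are
the straw-induced major CAZymes — and a small non-CAZy "mixed-up" subset
(fold 4). Replicates multiply expected fractions by log-normal jitter
(σ = 0.05, library-prep-level variability); fractions are renormalised to
sum to one per species-sample.

**Reads.** Fragment species ~ multinomial(mixture proportions), gene ~
expected fractions, length ~ Normal(250, 30) clipped at the read length
(fragments longer than the transcript are resampled up to five times, then
truncated, with a warning), position uniform within the spliced
transcript. The library is dUTP-style directional: read 2 carries the
transcript sense, read 1 its reverse complement. Substitution errors at a
fixed 0.1% per base; constant Q30 quality strings (assignment ignores
qualities). An exact truth record (species, gene, genomic interval,
strand) is emitted per fragment.

What the generator does **not** model: indels, introns/splice junctions,
repeat families, GC or positional coverage bias, quality-dependent errors,
rRNA/adapter contamination, or between-species gene content differences
(all genomes share coordinates and gene structure). Passing tests
therefore demonstrate correctness of the quantification logic under a
clean, coordinate-matched divergence model — not robustness to structural
variation or alignment artefacts in real genomes.

## Species assignment

The composite reference concatenates all genomes with `species|contig`
names and indexes every forward-strand 31-mer (2-bit packed, sorted
array + binary search). A repeat-mask interval input is accepted and is a
no-op by default, since the generator plants no repeats. For each read
pair, k-mer hits are counted per species over both mates and both
orientations; a k-mer occurring in several species counts for each.
Verdicts:

- **unmapped** — best species has fewer than `min_hits` (default 2) hits;
- **unique(s)** — `hits(s') ≤ margin · hits(s)` for every other species
  `s'`;
- **ambiguous** — otherwise. `margin = 0` reproduces the strict "any
  second-species hit voids uniqueness" rule, under which equally-matching
  duplicated genomes always tie.

The default `margin = 0.5` is a 2:1 dominance rule chosen from k-mer
survival arithmetic: at 10% divergence a 31-mer is species-informative
with probability `1 − 0.9^31 ≈ 0.96`, but substitution sites cluster, and
a conserved run of `g` bases contributes `g − 30` shared k-mers; requiring
2:1 dominance only surrenders pairs in which a large part of both mates
lies in such a run (a percent-level tail), while misassignment stays
essentially impossible because shared k-mers support the true species too
(the worst error-driven case observed in analysis keeps the true species
above 70% of the wrong species' count). Read length must be ≥ k; all
reads in a batch must have equal length.

The fragment locus is inferred from the modal alignment diagonal
(reference position minus read offset) of k-mers exclusive to the winning
species and unique in the reference, taken per mate in its best-supported
orientation; the fragment interval spans both mates, and the strand
follows the directional protocol (mate 1 antisense). Counting is
htseq-union-like: a fragment counts once for gene *g* if its interval
overlaps exons of *g* and of no other strand-compatible gene
(`stranded_mode="reverse"` by default; `"none"` disables the strand
check); overlap with two or more genes discards it as gene-ambiguous,
and no exon overlap leaves it uncounted.

## FPKM

`FPKM_gj = C_gj · 10⁹ / (L_g · M_sj)` with `M_sj` the species' own total
of uniquely assigned fragments counted onto its gene models — intergenic
and gene-ambiguous unique fragments are excluded from the denominator.
This makes `Σ_g FPKM_gj · L_g/10³ = 10⁶` an exact identity per
species-sample and makes FPKM invariant to uniform count scaling.
Samples with `M_sj = 0` yield all-missing columns with a warning; genes
without a length are rejected rather than imputed. CAZy aggregation sums
FPKM over families whose class prefix is in {GH, CE, PL, AA} and not GT
(glycosyltransferases do not degrade plant biomass); replicate summaries
report mean ± SE = sd/√n, n ≥ 2 required.

## Differential expression

Size factors are plain median-of-ratios (median over genes nonzero in all
samples of the count divided by the gene's geometric mean). The test is a
two-group negative-binomial Wald test on normalised counts: per-gene
dispersion by method of moments on the pooled within-group variance,
**floored at a trend** (the median gene-wise dispersion in 20 log-mean
quantile bins; the gene uses `max(trend, gene-wise)`), then a delta-method
Wald statistic on `log2((m₂+ε)/(m₁+ε))` with NB variance `μ + αμ²` and a
two-sided normal p-value. ε = 0.5 keeps fold changes finite at zero
counts. The trend floor matters: with three replicates per group the raw
moment estimate is noisy enough that a plain Wald test roughly doubles the
nominal type-I error, while with the floor the null rejection rate is
close to nominal (validated by simulation in the test suite at α = 0.01
and 0.05) and large planted effects retain essentially full power.
Degenerate genes (zero variance in both groups, equal means) get p = 1.
No shrinkage of fold changes, no GLM, no outlier handling — this is a
calibrated stand-in for a full DE framework, validated by calibration
rather than concordance with any external tool.

The DE call applies three filters: fold ≥ 2 on normalised counts (not
FPKM), Benjamini–Hochberg `p_adj < 0.05`, and mean FPKM ≥ 1 in the test
condition for up-calls / the control condition for down-calls. Relaxing
any threshold can only add calls (tested monotonicity).

## Clustering and enrichment

Heatmap gene selection retains genes significantly changed versus the
glucose control (`p_adj < 0.05` in at least one straw condition) with
FPKM ≥ 1 in at least one straw condition, optionally restricted by
annotation (e.g. CAZy only); the glucose column can be retained for
display. Values are `log2(x + 1)` (base 2 and offset 1 chosen as the
standard for FPKM heatmaps; zeros map to zero). The distance is
`d = 1 − r_u` with the uncentered correlation
`r_u = Σxy / √(Σx²·Σy²)`; unlike Pearson it does not centre the data, so
magnitude matters; `d ∈ [0, 2]` and anticorrelated profiles exceed 1.
All-zero rows are rejected by name. Complete linkage uses
`scipy.cluster.hierarchy`; ties (measure-zero on continuous data) follow
scipy's deterministic ordering. Flat clusters come from a count or height
cut; dendrograms export to Newick. Enrichment is the upper-tail
hypergeometric `P[X ≥ k]` per term over a flat term map (no ontology
propagation), BH-adjusted across terms; terms with `K = 0` in the
background score p = 1.

## qPCR marker quantification and biomass

Standard curves are least-squares lines `Ct = b + m·log10(copies)` on a
dilution series (default: ten five-fold dilutions from 5×10⁷ copies);
efficiency `E = 10^(−1/m) − 1`, r² and the dynamic range are reported,
below-detection wells (NaN Ct) are excluded from fits and flagged on
inversion, and values outside the standard range are flagged. The Ct model
is log-linear only — no sigmoid amplification-curve fitting, no melt
analysis, no primer design. Probe specificity is modelled as a boolean
cross-reactivity matrix in the plate simulator.

Species mixture shares are marker copies divided by the total over
species; predicted read yield is share × planned total reads (the
proportional-share formalisation of using rRNA shares to plan sequencing
depth). Pairwise ratios and their fold change between time points are
reported. Because all species share the same rRNA copy number per genome
in the simulator, shares are a clean proxy for RNA proportions; in real
data copy-number differences between species would bias shares, which is
why the package validates shares against realized read fractions rather
than asserting absolute accuracy.

Biomass estimation fits `Ct` versus `log10(mg dry weight)` on standards
spanning 2–50 mg; samples measured on the same gDNA dilution (default
1/500, retained to convert to absolute locus copies) invert the curve to
aliquot milligrams, and the flask total scales by the inverse aliquot
fraction. On noiseless simulated data the roundtrip is exact.

## Assays

pNP activity is `released ρmol / (minutes · μl filtrate)` with the 3 h
default incubation; DNS sugar release converts plate signals through a
fitted linear glucose curve and subtracts straw and filtrate controls
(negative results are flagged below-background, never clamped); both the
pNP and glucose conversions go through fitted standard curves rather than
molar-absorptivity shortcuts (the pNP curve is user-supplied).
Per-biomass normalisation divides by dry weight. All three operations are
homogeneous of degree one (or minus one) in their inputs and are
property-tested as such.

## Numerical and interface choices

- Seeded `numpy.random.Generator` throughout; per-sample read seeds derive
  from the study seed and a CRC32 of the sample id, so outputs are
  bit-reproducible and independent of sample order.
- K-mers are 2-bit packed into uint64 (k ≤ 31 fits with headroom); the
  index stores a species bitmask (≤ 16 species), first-occurrence position
  and a multi-occurrence flag per distinct k-mer.
- FPKM, distances and curve fits are plain float64 linear algebra; the
  uncentered-correlation matrix is symmetrised and clipped at 0 to remove
  float noise.
- Estimator-style classes (`KmerSpeciesClassifier`,
  `NegativeBinomialWaldDE`, `UncenteredCorrelationLinkage`,
  `StandardCurve`, `BiomassEstimator`) follow scikit-learn conventions
  (constructor parameters, `fit`, trailing-underscore fitted attributes);
  module-level functions wrap them for script use. The generator and assay
  arithmetic are plain functions — they are not fit/predict shaped.

## Known limitations

- The k-mer vote is a stand-in for spliced alignment with a MAPQ
  threshold; it is exact-match only (an error or SNP breaks all k-mers it
  touches) and its margin rule is not claimed equivalent to any aligner's
  multi-mapping behaviour for near-identical paralogues.
- FPKM values are comparable within a species, not between species.
- The DE module handles exactly two groups with ≥ 2 replicates each; no
  multi-factor designs, dispersion shrinkage toward a fitted mean-variance
  curve beyond the binned trend, or independent filtering.
- Enrichment uses a flat term map; no GO DAG propagation.
- Planted effect sizes are free configuration of the generator, not claims
  about any real culture.
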