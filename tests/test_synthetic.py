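"""Generator behaviour: genomes, expression, reads, qPCR plates."""

import numpy as np
import pandas as pd
import pytest

import cocultureseq as cq
from cocultureseq import io
from cocultureseq.config import SampleSpec, build_sample_sheet, mixture_condition
from cocultureseq.expression import LABEL_MIXED_DOWN, LABEL_NONE
from cocultureseq.qpcr import CtCurveParams, default_standard_copies


def small_cfg(**kw):
    base = dict(n_species=2, genome_length_bp=12_000, n_genes=10,
                gene_length_range=(300, 500), depth_mono=500, depth_mixed=500,
                mixtures=[(0, 1)], seed=3,
                effect_config={"n_straw_induced": 2, "n_mixed_down": 1, "n_mixed_up": 1})
    base.update(kw)
    return cq.SimulationConfig(**base)


class TestGenomes:
    def test_zero_divergence_gives_identical_contigs(self):
        g = cq.generate_genomes(small_cfg(divergence=0.0))
        assert g[0].contigs["chr1"] == g[1].contigs["chr1"]

    def test_seeded_runs_are_byte_identical(self, tmp_path):
        outs = []
        for run in ("a", "b"):
            g = cq.generate_genomes(small_cfg())[0]
            fa, gff = tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3"
            io.write_fasta(g, fa)
            io.write_gff3(g, gff)
            outs.append((fa.read_bytes(), gff.read_bytes()))
        assert outs[0] == outs[1]

    @pytest.mark.parametrize("d", [0.01, 0.10])
    def test_pairwise_divergence_matches_configured_rate(self, d):
        cfg = cq.SimulationConfig(n_species=3, genome_length_bp=100_000, n_genes=20,
                                  divergence=d, seed=5)
        g = cq.generate_genomes(cfg)
        for i in range(3):
            for j in range(i + 1, 3):
                assert cq.pairwise_divergence(g[i], g[j]) == pytest.approx(d, abs=0.01)

    def test_gene_models_within_bounds_and_disjoint(self, tiny_genomes):
        for genome in tiny_genomes:
            L = genome.contig_length("chr1")
            spans = sorted(g.span for g in genome.gene_models)
            prev_end = 0
            for start, end in spans:
                assert 1 <= start <= end <= L
                assert start > prev_end
                prev_end = end

    def test_markers_discriminate_every_species_pair(self, tiny_genomes):
        m = tiny_genomes[0].marker_rrna
        assert m.copy_number > 1
        assert all(g.marker_single_copy.copy_number == 1 for g in tiny_genomes)
        for i, a in enumerate(tiny_genomes):
            for b in tiny_genomes[i + 1:]:
                diffs = [
                    off for off in m.discriminating_positions
                    if a.contigs["chr1"][m.start - 1 + off] != b.contigs["chr1"][m.start - 1 + off]
                ]
                assert diffs, f"{a.species_id} vs {b.species_id} not discriminated"

    def test_genome_too_small_raises(self):
        with pytest.raises(ValueError, match="cannot host|too small"):
            cq.generate_genomes(small_cfg(genome_length_bp=2_000))

    def test_cazy_annotation_has_gt_and_degradative_families(self, tiny_genomes):
        for genome in tiny_genomes:
            fams = {a["cazy"] for a in genome.annotations.values() if a["cazy"]}
            classes = {"".join(c for c in f if c.isalpha()) for f in fams}
            assert "GT" in classes
            assert len(classes & {"GH", "CE", "PL", "AA"}) >= 2


class TestExpression:
    def test_unit_folds_give_identical_conditions(self):
        cfg = small_cfg(replicate_sigma=0.0,
                        effect_config={"straw_induction_fold": 1.0, "mixed_down_fold": 1.0,
                                       "mixed_up_fold": 1.0})
        expr = cq.simulate_expression(cfg, cq.generate_genomes(cfg))
        f = expr.fractions
        for sp in ("sp1", "sp2"):
            np.testing.assert_allclose(f[(sp, "glucose", 1)], f[(sp, "straw", 1)])
            np.testing.assert_allclose(f[(sp, "glucose", 1)], f[(sp, "mixed", 1)])

    def test_fractions_sum_to_one(self, tiny_expression):
        for frac in tiny_expression.fractions.values():
            assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_mixed_down_fold_before_renormalisation(self):
        cfg = small_cfg(replicate_sigma=0.0)
        genomes = cq.generate_genomes(cfg)
        expr = cq.simulate_expression(cfg, genomes)
        fold = cfg.effect_config.mixed_down_fold
        for sp in ("sp1", "sp2"):
            down = expr.genes_with_label(sp, LABEL_MIXED_DOWN)
            ref = expr.genes_with_label(sp, LABEL_NONE)[0]
            gi = {g: i for i, g in enumerate(expr.gene_ids[sp])}
            straw = expr.fractions[(sp, "straw", 1)]
            mixed = expr.fractions[(sp, "mixed", 1)]
            for g in down:
                # renormalisation constants cancel against an unaffected gene
                ratio = (straw[gi[g]] / mixed[gi[g]]) / (straw[gi[ref]] / mixed[gi[ref]])
                assert ratio == pytest.approx(fold, rel=1e-9)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="must be > 0"):
            small_cfg(effect_config={"mixed_down_fold": 0.0})


class TestReads:
    def test_depth_conservation(self, tiny_cfg, tiny_genomes, tiny_expression):
        sample = SampleSpec("s", mixture_condition(["sp1", "sp2", "sp3"]), 1,
                            {"sp1": 1 / 3, "sp2": 1 / 3, "sp3": 1 / 3}, 1000)
        reads = cq.simulate_read_pairs(tiny_cfg, tiny_genomes, tiny_expression, sample, seed=1)
        assert len(reads.ids) == len(reads.r1) == len(reads.r2) == 1000
        assert len(reads.truth) == 1000
        assert reads.truth["fragment_id"].is_unique

    def test_degenerate_mixture_yields_single_species(self, tiny_cfg, tiny_genomes, tiny_expression):
        sample = SampleSpec("s", "sp2:straw_mono", 1, {"sp2": 1.0}, 300)
        reads = cq.simulate_read_pairs(tiny_cfg, tiny_genomes, tiny_expression, sample, seed=2)
        assert set(reads.truth["species"]) == {"sp2"}

    def test_species_fractions_within_three_binomial_sd(self, tiny_cfg, tiny_genomes, tiny_expression):
        p = 0.8
        n = 50_000
        sample = SampleSpec("s", mixture_condition(["sp1", "sp2"]), 1,
                            {"sp1": p, "sp2": 1 - p}, n)
        reads = cq.simulate_read_pairs(tiny_cfg, tiny_genomes, tiny_expression, sample, seed=3)
        frac = (reads.truth["species"] == "sp1").mean()
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_truth_intervals_match_read_sequences(self):
        from cocultureseq.genomes import reverse_complement

        cfg = small_cfg(error_rate=0.0)
        genomes = cq.generate_genomes(cfg)
        expr = cq.simulate_expression(cfg, genomes)
        sample = SampleSpec("s", "sp1:straw_mono", 1, {"sp1": 1.0}, 50)
        reads = cq.simulate_read_pairs(cfg, genomes, expr, sample, seed=4)
        genome = genomes[0]
        for i, row in reads.truth.iterrows():
            frag = genome.contigs[row["contig"]][row["start"] - 1 : row["end"]]
            if row["strand"] == "-":
                frag = reverse_complement(frag)
            # read 2 carries the transcript sense, read 1 its reverse complement
            assert reads.r2[i] == frag[: cfg.read_length]
            assert reads.r1[i] == reverse_complement(frag[-cfg.read_length:])


class TestQpcrSim:
    def test_single_copy_ct_equals_intercept(self):
        curve = CtCurveParams(intercept=40.0)
        assert float(curve.ct(1.0)) == pytest.approx(40.0)

    def test_tenfold_copies_shift_ct_by_slope(self):
        curve = CtCurveParams(slope=-3.321928, intercept=40.0)
        assert float(curve.ct(10.0) - curve.ct(100.0)) == pytest.approx(3.321928)

    def test_default_standard_series_is_ten_fivefold_dilutions(self):
        copies = default_standard_copies()
        assert len(copies) == 10
        np.testing.assert_allclose(copies, 5e7 / 5.0 ** np.arange(10))

    def test_zero_copy_well_reports_no_amplification(self):
        plate = cq.simulate_qpcr_plate(["spA"], {"s1": {"spA": 0.0}})
        assert np.isnan(plate["ct"]).all()

    def test_off_target_wells_do_not_amplify(self):
        plate = cq.simulate_qpcr_plate(["spA", "spB"], {"s1": {"spA": 1e5}})
        by_assay = plate.set_index("assay")["ct"]
        assert np.isfinite(by_assay["spA"])
        assert np.isnan(by_assay["spB"])


class TestGdnaSim:
    def test_zero_weight_gives_no_amplification(self):
        sim = cq.simulate_gdna_biomass({"spA": 0.0}, seed=0)
        assert np.isnan(sim.samples["ct"]).all()

    def test_doubling_weight_doubles_copies(self):
        sim = cq.simulate_gdna_biomass({"a": 10.0, "b": 20.0}, seed=0)
        cts = sim.samples.set_index("species")["ct"]
        dct = cts["b"] - cts["a"]
        assert dct == pytest.approx(sim.curve.slope * np.log10(2.0))

    def test_standards_span_2_to_50_mg(self):
        sim = cq.simulate_gdna_biomass({"a": 10.0}, seed=0)
        assert sim.standards["mg"].min() == 2.0
        assert sim.standards["mg"].max() == 50.0


def test_sample_sheet_matches_design():
    cfg = cq.SimulationConfig(n_species=3, genome_length_bp=30_000, n_genes=20, seed=0)
    samples = build_sample_sheet(cfg)
    # 3 species x 2 mono conditions x 3 reps + (3 pairs + 1 trio) x 3 reps
    assert len(samples) == 18 + 12
    mono = [s for s in samples if len(s.proportions) == 1]
    mixed = [s for s in samples if len(s.proportions) > 1]
    assert all(s.depth == cfg.depth_mono for s in mono)
    assert all(s.depth == cfg.depth_mixed for s in mixed)
    for s in samples:
        assert sum(s.proportions.values()) == pytest.approx(1.0, abs=1e-9)


def test_config_yaml_roundtrip(tmp_path):
    cfg = cq.SimulationConfig(n_species=2, genome_length_bp=15_000, n_genes=12, seed=9)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    loaded = cq.SimulationConfig.from_yaml(path)
    assert loaded.n_species == 2 and loaded.seed == 9
    assert loaded.effect_config == cfg.effect_config
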