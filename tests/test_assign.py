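"""Composite reference, k-mer vote assignment, fragment counting."""

import numpy as np
import pandas as pd
import pytest

import cocultureseq as cq
from cocultureseq.assign import (
    VERDICT_AMBIGUOUS,
    VERDICT_UNIQUE,
    VERDICT_UNMAPPED,
    build_composite_reference,
    count_fragments,
)
from cocultureseq.config import SampleSpec, mixture_condition
from cocultureseq.genomes import GeneModel, MarkerLocus, SpeciesGenome, reverse_complement


def make_genome(species_id: str, seq: str, genes=()) -> SpeciesGenome:
    dummy = MarkerLocus(f"{species_id}_m", "chr1", 1, 1, 1)
    return SpeciesGenome(species_id, {"chr1": seq}, list(genes), dummy, dummy)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def brute_force_assign(r1, r2, genomes, k, min_hits, margin):
    """Independent oracle: count k-mer hits by substring search on each genome."""
    hits = {}
    for g in genomes:
        total = 0
        contigs = list(g.contigs.values())
        for read in (r1, r2):
            for oriented in (read, reverse_complement(read)):
                for o in range(len(oriented) - k + 1):
                    km = oriented[o : o + k]
                    if any(km in c for c in contigs):
                        total += 1
        hits[g.species_id] = total
    ranked = sorted(hits.items(), key=lambda kv: -kv[1])
    best_sp, best = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else 0
    if best < min_hits:
        return VERDICT_UNMAPPED, ""
    if second <= margin * best:
        return VERDICT_UNIQUE, best_sp
    return VERDICT_AMBIGUOUS, ""


class TestCompositeReference:
    def test_concatenation_length_and_tagging(self, rng):
        g1 = make_genome("a", random_seq(rng, 10_000))
        g2 = make_genome("b", random_seq(rng, 10_000))
        ref = build_composite_reference([g1, g2], k=31)
        assert ref.total_length == 20_000
        assert ref.contig_names == ["a|chr1", "b|chr1"]
        assert [ref.species_ids[i] for i in ref.contig_species] == ["a", "b"]

    def test_unique_kmer_has_single_entry(self, rng):
        seq = random_seq(rng, 500)
        ref = build_composite_reference(
            [make_genome("a", seq), make_genome("b", random_seq(rng, 500))], k=31
        )
        # nearly all k-mers of a 500 bp random sequence are unique
        assert (~ref.multi).mean() > 0.95
        single = ref.species_mask[~ref.multi]
        assert set(np.unique(single)) <= {1, 2}

    def test_duplicate_species_id_rejected(self, rng):
        g = make_genome("a", random_seq(rng, 200))
        with pytest.raises(ValueError, match="duplicate"):
            build_composite_reference([g, g])

    def test_needs_two_genomes(self, rng):
        with pytest.raises(ValueError, match="two genomes"):
            build_composite_reference([make_genome("a", random_seq(rng, 200))])


class TestAssignment:
    def test_discriminating_site_yields_unique_verdict(self, rng):
        seq_a = random_seq(rng, 400)
        pos = 200
        other = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq_a[pos]]
        seq_b = seq_a[:pos] + other + seq_a[pos + 1:]
        genomes = [make_genome("a", seq_a), make_genome("b", seq_b)]
        clf = cq.KmerSpeciesClassifier(k=31, min_hits=1, margin=0.0).fit(genomes)
        r1 = seq_a[pos - 20 : pos + 20]  # covers the site: every k-mer does too
        r2 = reverse_complement(r1)
        tab = clf.assign([r1], [r2])
        assert tab.loc[0, "verdict"] == VERDICT_UNIQUE
        assert tab.loc[0, "species"] == "a"

    def test_identical_genomes_are_ambiguous(self, rng):
        seq = random_seq(rng, 2_000)
        genomes = [make_genome("a", seq), make_genome("b", seq)]
        clf = cq.KmerSpeciesClassifier().fit(genomes)
        reads = [seq[i : i + 75] for i in range(0, 1000, 100)]
        mates = [reverse_complement(r) for r in reads]
        tab = clf.assign(reads, mates)
        assert (tab["verdict"] == VERDICT_AMBIGUOUS).all()

    def test_verdicts_partition_fragments(self, tiny_cfg, tiny_genomes, tiny_expression, tiny_classifier):
        sample = SampleSpec("s", mixture_condition(["sp1", "sp2", "sp3"]), 1,
                            {sp: 1 / 3 for sp in ("sp1", "sp2", "sp3")}, 2000)
        reads = cq.simulate_read_pairs(tiny_cfg, tiny_genomes, tiny_expression, sample, seed=8)
        tab = tiny_classifier.assign(reads.r1, reads.r2, ids=reads.ids)
        counts = tab["verdict"].value_counts()
        assert counts.sum() == 2000
        assert set(counts.index) <= {VERDICT_UNIQUE, VERDICT_AMBIGUOUS, VERDICT_UNMAPPED}

    def test_random_garbage_is_unmapped(self, tiny_classifier, rng):
        reads = [random_seq(rng, 75) for _ in range(20)]
        tab = tiny_classifier.assign(reads, [random_seq(rng, 75) for _ in range(20)])
        assert (tab["verdict"] == VERDICT_UNMAPPED).mean() > 0.9

    def test_empty_input_warns_and_returns_empty(self, tiny_classifier):
        with pytest.warns(UserWarning, match="empty"):
            tab = tiny_classifier.assign([], [])
        assert len(tab) == 0

    def test_reads_shorter_than_k_rejected(self, tiny_classifier):
        with pytest.raises(ValueError, match="< k"):
            tiny_classifier.assign(["ACGT"], ["ACGT"])

    def test_verdicts_match_brute_force_oracle(self, rng):
        n_cases = 60
        mismatches = []
        for case in range(n_cases):
            L = int(rng.integers(300, 1200))
            anc = random_seq(rng, L)
            genomes = []
            for sp in ("a", "b", "c"):
                seq = list(anc)
                d = float(rng.uniform(0, 0.15))
                for i in np.nonzero(rng.random(L) < d)[0]:
                    seq[i] = "ACGT"[(("ACGT".index(seq[i])) + int(rng.integers(1, 4))) % 4]
                genomes.append(make_genome(sp, "".join(seq)))
            k = int(rng.choice([15, 21]))
            min_hits, margin = 2, float(rng.choice([0.0, 0.25]))
            clf = cq.KmerSpeciesClassifier(k=k, min_hits=min_hits, margin=margin).fit(genomes)
            rl = int(rng.integers(k, 41))
            src = genomes[int(rng.integers(0, 3))].contigs["chr1"]
            start = int(rng.integers(0, len(src) - rl))
            r1 = src[start : start + rl]
            r2 = reverse_complement(r1)
            tab = clf.assign([r1], [r2])
            got = (tab.loc[0, "verdict"], tab.loc[0, "species"])
            want = brute_force_assign(r1, r2, genomes, k, min_hits, margin)
            if got != want:
                mismatches.append((case, got, want))
        assert not mismatches

    def test_inferred_locus_matches_truth(self, tiny_cfg, tiny_genomes, tiny_expression, tiny_classifier):
        sample = SampleSpec("s", "sp1:straw_mono", 1, {"sp1": 1.0}, 500)
        reads = cq.simulate_read_pairs(tiny_cfg, tiny_genomes, tiny_expression, sample, seed=9)
        tab = tiny_classifier.assign(reads.r1, reads.r2, ids=reads.ids)
        merged = tab.merge(reads.truth, on="fragment_id", suffixes=("_hat", ""))
        uniq = merged[merged["verdict"] == VERDICT_UNIQUE]
        assert len(uniq) > 400
        assert (uniq["species_hat"] == uniq["species"]).all()
        assert (uniq["contig_hat"] == uniq["contig"]).all()
        assert (uniq["start_hat"] == uniq["start"]).mean() > 0.99
        assert (uniq["strand_hat"] == uniq["strand"]).mean() > 0.99


class TestCountFragments:
    @staticmethod
    def asg_row(fid, sp, contig, start, end, strand):
        return {"fragment_id": fid, "verdict": VERDICT_UNIQUE, "species": sp,
                "contig": contig, "start": start, "end": end, "strand": strand}

    @pytest.fixture()
    def models(self):
        return {
            "a": [
                GeneModel("a_g1", "chr1", "+", ((100, 500),)),
                GeneModel("a_g2", "chr1", "-", ((450, 900),)),  # overlaps a_g1
                GeneModel("a_g3", "chr1", "+", ((2000, 2500),)),
            ]
        }

    def test_fragment_inside_single_exon_counts_once(self, models):
        asg = pd.DataFrame([self.asg_row("f1", "a", "chr1", 150, 400, "+")])
        fc = count_fragments(asg, models)
        assert fc.counts["a"]["a_g1"] == 1
        assert fc.counted_total["a"] == 1 and fc.unique_total["a"] == 1

    def test_fragment_spanning_two_genes_discarded(self, models):
        asg = pd.DataFrame([self.asg_row("f1", "a", "chr1", 400, 600, "+")])
        fc = count_fragments(asg, models, stranded_mode="none")
        assert fc.counts["a"].sum() == 0
        assert fc.gene_ambiguous["a"] == 1

    def test_strand_filter_resolves_overlap(self, models):
        # on the '+' strand only a_g1 is compatible despite positional overlap
        asg = pd.DataFrame([self.asg_row("f1", "a", "chr1", 460, 490, "+")])
        fc = count_fragments(asg, models, stranded_mode="reverse")
        assert fc.counts["a"]["a_g1"] == 1

    def test_intergenic_fragment_uncounted(self, models):
        asg = pd.DataFrame([self.asg_row("f1", "a", "chr1", 1000, 1200, "+")])
        fc = count_fragments(asg, models)
        assert fc.counted_total["a"] == 0
        assert fc.unique_total["a"] == 1

    def test_unknown_contig_raises(self, models):
        asg = pd.DataFrame([self.asg_row("f1", "a", "chrX", 10, 20, "+")])
        with pytest.raises(KeyError, match="unknown contig"):
            count_fragments(asg, models)


class TestConfusion:
    def test_perfect_assignment_has_zero_offdiagonal(self):
        truth = pd.DataFrame({"fragment_id": ["f1", "f2"], "species": ["a", "b"]})
        asg = pd.DataFrame({
            "fragment_id": ["f1", "f2"], "verdict": [VERDICT_UNIQUE] * 2,
            "species": ["a", "b"],
        })
        out = cq.assignment_confusion(truth, asg)
        assert out["rates"]["misassignment_rate"] == 0.0
        assert out["rates"]["unique_correct_fraction"] == 1.0

    def test_all_ambiguous(self):
        truth = pd.DataFrame({"fragment_id": ["f1", "f2"], "species": ["a", "a"]})
        asg = pd.DataFrame({
            "fragment_id": ["f1", "f2"], "verdict": [VERDICT_AMBIGUOUS] * 2, "species": ["", ""],
        })
        out = cq.assignment_confusion(truth, asg)
        assert out["rates"]["misassignment_rate"] == 0.0
        assert out["rates"]["unique_fraction"] == 0.0
        assert out["rates"]["ambiguous_fraction"] == 1.0

    def test_rates_partition(self):
        truth = pd.DataFrame({"fragment_id": list("abcd"), "species": ["a"] * 4})
        asg = pd.DataFrame({
            "fragment_id": list("abcd"),
            "verdict": [VERDICT_UNIQUE, VERDICT_UNIQUE, VERDICT_AMBIGUOUS, VERDICT_UNMAPPED],
            "species": ["a", "b", "", ""],
        })
        r = cq.assignment_confusion(truth, asg)["rates"]
        assert r["unique_fraction"] + r["ambiguous_fraction"] + r["unmapped_fraction"] == pytest.approx(1.0)
        assert r["misassignment_rate"] == pytest.approx(0.25)

    def test_id_mismatch_raises(self):
        truth = pd.DataFrame({"fragment_id": ["f1"], "species": ["a"]})
        asg = pd.DataFrame({"fragment_id": ["f2"], "verdict": [VERDICT_UNIQUE], "species": ["a"]})
        with pytest.raises(ValueError, match="different fragments"):
            cq.assignment_confusion(truth, asg)
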