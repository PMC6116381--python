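import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutaccum import spectrum
from mutaccum.io_formats import AnnotatedGenome, Gene, MutationCall
from mutaccum.spectrum import (
    NA,
    classify_bps,
    classify_indel,
    revcomp,
    six_type_of,
    tabulate_spectrum,
)


class TestSixType:
    @pytest.mark.parametrize("ref,alt,label,tstv", [
        ("A", "G", "A:T>G:C", "transition"),
        ("T", "C", "A:T>G:C", "transition"),   # reverse complement of A>G
        ("G", "A", "G:C>A:T", "transition"),
        ("C", "A", "G:C>T:A", "transversion"),
        ("A", "T", "A:T>T:A", "transversion"),
        ("G", "C", "G:C>C:G", "transversion"),
    ])
    def test_strand_collapsed_labels(self, ref, alt, label, tstv):
        assert six_type_of(ref, alt) == (label, tstv)

    def test_every_mutation_equals_its_reverse_complement(self):
        comp = dict(zip("ACGT", "TGCA"))
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert six_type_of(ref, alt) == six_type_of(comp[ref], comp[alt])

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            six_type_of("N", "A")
        with pytest.raises(ValueError):
            six_type_of("A", "A")


class TestClassifyBPS:
    def test_synonymous_third_position(self, toy_genome):
        # codon 2 is GAT (Asp); GAT->GAC third-position T>C is synonymous
        call = MutationCall("l", 6, "T", "C")
        cls = classify_bps(call, toy_genome)
        assert (cls.region, cls.effect, cls.conservation) == ("coding", "synonymous", NA)

    def test_conservative_nonsynonymous(self, toy_genome):
        # GAT (Asp) -> GAA (Glu): BLOSUM62(D, E) = +2, conservative
        call = MutationCall("l", 6, "T", "A")
        cls = classify_bps(call, toy_genome)
        assert (cls.effect, cls.conservation) == ("nonsynonymous", "conservative")

    def test_nonconservative_nonsynonymous(self, toy_genome):
        # GAT (Asp) -> GTT (Val): BLOSUM62(D, V) = -3, non-conservative
        call = MutationCall("l", 5, "A", "T")
        cls = classify_bps(call, toy_genome)
        assert (cls.effect, cls.conservation) == ("nonsynonymous", "non-conservative")

    def test_stop_gain_is_nonconservative(self, toy_genome):
        # GAT (Asp) -> TAT? no: use codon GAT -> TAA needs 2 changes; instead
        # mutate GAT first position G>T: TAT (Tyr). Use the stop at the end:
        # TAA -> CAA (Gln) is stop-loss, nonsynonymous and non-conservative.
        call = MutationCall("l", 28, "T", "C")
        cls = classify_bps(call, toy_genome)
        assert (cls.effect, cls.conservation) == ("nonsynonymous", "non-conservative")

    def test_noncoding_site(self):
        g = AnnotatedGenome("x", "ACGTACGTACGT", [Gene("g", 1, 6, "+")])
        cls = classify_bps(MutationCall("l", 10, "C", "T"), g)
        assert (cls.region, cls.effect, cls.conservation) == ("noncoding", NA, NA)

    def test_minus_strand_gene_via_reverse_complement(self):
        # sense CDS = ATG GAT TAA on the minus strand: genomic segment is its
        # reverse complement. Genomic C>T at the codon-2 third position is
        # sense G>A? Build and check against direct sense-strand reasoning.
        sense = "ATG" + "GAT" + "TAA"
        genomic = revcomp(sense)
        g = AnnotatedGenome("x", genomic, [Gene("g", 1, 9, "-")])
        # sense position 6 (T of GAT) = genomic position 9 - 6 + 1 = 4,
        # genomic base complement(T)=A; sense T>C == genomic A>G
        assert genomic[3] == "A"
        cls = classify_bps(MutationCall("l", 4, "A", "G"), g)
        assert cls.effect == "synonymous"          # GAT -> GAC, still Asp
        assert cls.six_type == "A:T>G:C"

    def test_reference_mismatch_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="reference mismatch"):
            classify_bps(MutationCall("l", 1, "C", "T"), toy_genome)

    def test_strand_symmetry_on_mirrored_genome(self, toy_genome):
        """Classifying on the reverse-complemented genome gives the same class."""
        L = len(toy_genome)
        mirror = AnnotatedGenome(
            "m", revcomp(toy_genome.sequence),
            [Gene("g1", L - g.end + 1, L - g.start + 1,
                  "-" if g.strand == "+" else "+") for g in toy_genome.genes],
        )
        comp = dict(zip("ACGT", "TGCA"))
        for pos in range(1, L + 1):
            ref = toy_genome.sequence[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                a = classify_bps(MutationCall("l", pos, ref, alt), toy_genome)
                b = classify_bps(
                    MutationCall("l", L - pos + 1, comp[ref], comp[alt]), mirror)
                assert a == b, (pos, ref, alt)


class TestClassifyIndel:
    def test_one_bp_insertion_pair(self):
        g = AnnotatedGenome("x", "ACGTACGTACGT")
        cls = classify_indel(MutationCall("l", 4, "", "G"), g)
        assert (cls.size, cls.direction, cls.pair) == (1, "gain", "G:C")

    def test_one_bp_deletion_in_run(self):
        g = AnnotatedGenome("x", "CCAAAACC")
        cls = classify_indel(MutationCall("l", 4, "A", ""), g, run_min_len=3)
        assert (cls.direction, cls.pair, cls.in_run) == ("loss", "A:T", True)

    def test_one_bp_insertion_adjacent_to_run(self):
        g = AnnotatedGenome("x", "CGAAAACG")
        # insertion of A after position 2 abuts the AAAA run
        cls = classify_indel(MutationCall("l", 2, "", "A"), g, run_min_len=3)
        assert cls.in_run is True
        # insertion of G there does not match the run base
        cls2 = classify_indel(MutationCall("l", 2, "", "G"), g, run_min_len=3)
        assert cls2.in_run is False

    def test_run_threshold_respected(self):
        g = AnnotatedGenome("x", "CCAAACC")
        assert classify_indel(MutationCall("l", 4, "A", ""), g, run_min_len=3).in_run
        assert not classify_indel(
            MutationCall("l", 4, "A", ""), g, run_min_len=4).in_run

    def test_multibase_deletion_pair_not_applicable(self):
        g = AnnotatedGenome("x", "ACGTACGTACGT")
        cls = classify_indel(MutationCall("l", 3, "GTA", ""), g)
        assert (cls.size, cls.direction, cls.pair) == (3, "loss", NA)

    def test_snv_rejected(self):
        g = AnnotatedGenome("x", "ACGT")
        with pytest.raises(ValueError):
            classify_indel(MutationCall("l", 1, "A", "G"), g)


class TestTabulate:
    def _classified(self, genome, calls):
        out = []
        for c in calls:
            if c.kind == "SNV":
                out.append((c, classify_bps(c, genome)))
            else:
                out.append((c, classify_indel(c, genome)))
        return out

    def test_empty_input_gives_zero_table(self):
        counts = tabulate_spectrum([], {"l1": "25C", "l2": "37C"})
        assert (counts.per_line.to_numpy() == 0).all()
        assert set(counts.per_line.index) == {"l1", "l2"}

    def test_transition_fraction_arithmetic(self, toy_genome):
        calls = [MutationCall("l1", 6, "T", "C")] * 87 + [MutationCall("l1", 6, "T", "A")] * 13
        counts = tabulate_spectrum(self._classified(toy_genome, calls), {"l1": "25C"})
        row = counts.per_line.loc["l1"]
        assert row["bps_total"] == 100
        assert row["transitions"] / row["bps_total"] == pytest.approx(0.87)

    def test_unknown_line_rejected(self, toy_genome):
        pairs = self._classified(toy_genome, [MutationCall("zz", 6, "T", "C")])
        with pytest.raises(ValueError, match="unknown line"):
            tabulate_spectrum(pairs, {"l1": "25C"})

    @settings(deadline=None, max_examples=25)
    @given(st.lists(
        st.tuples(st.integers(1, 30), st.sampled_from("ACGT"), st.booleans()),
        max_size=60,
    ))
    def test_count_invariants_on_fuzzed_calls(self, events):
        """Marginal sums hold for arbitrary mixes of SNVs and indels."""
        genome = AnnotatedGenome(
            "f", "ATG" + "GAT" * 8 + "TAA", [Gene("g1", 1, 30, "+")])
        pairs = []
        for pos, alt, is_indel in events:
            if is_indel:
                c = MutationCall("l1", pos, "", alt)
                pairs.append((c, classify_indel(c, genome)))
            else:
                ref = genome.sequence[pos - 1]
                if ref == alt:
                    continue
                c = MutationCall("l1", pos, ref, alt)
                pairs.append((c, classify_bps(c, genome)))
        counts = tabulate_spectrum(pairs, {"l1": "37C"})
        counts.validate()   # raises on any violated marginal
        row = counts.per_line.loc["l1"]
        assert row["mutations_total"] == len(pairs)


def test_site_effect_table_matches_classifier(small_genome):
    """Vectorized per-site effect codes agree with classify_bps site by site."""
    table = spectrum.site_effect_table(small_genome)
    rng = np.random.default_rng(0)
    positions = rng.integers(0, len(small_genome), size=300)
    code_of = {
        ("noncoding", NA): spectrum.SITE_NONCODING,
        ("coding", "synonymous"): spectrum.SITE_SYNONYMOUS,
        ("coding", "conservative"): spectrum.SITE_NONSYN_CONSERVATIVE,
        ("coding", "non-conservative"): spectrum.SITE_NONSYN_NONCONSERVATIVE,
    }
    for p0 in positions:
        ref = small_genome.sequence[p0]
        for ai, alt in enumerate("ACGT"):
            if alt == ref:
                assert table[p0, ai] == -1
                continue
            cls = classify_bps(MutationCall("l", int(p0) + 1, ref, alt), small_genome)
            key = (cls.region, cls.conservation if cls.effect == "nonsynonymous"
                   else (cls.effect if cls.region == "coding" else NA))
            assert table[p0, ai] == code_of[key], (p0, ref, alt, cls)
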