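import dataclasses
import math

import numpy as np
import pytest

from mutaccum import synthetic_data as synth
from mutaccum.spectrum import SIX_TYPES, classify_bps, six_type_of


class TestGenerateGenome:
    def test_stated_length_and_no_genes_means_noncoding(self):
        g = synth.generate_genome(synth.GenomeSpec(length=10_000, n_genes=0, seed=1))
        assert len(g) == 10_000
        assert g.coding_fraction == 0.0

    def test_gc_within_one_point_of_target(self):
        for seed in range(4):
            g = synth.generate_genome(synth.GenomeSpec(
                length=50_000, n_genes=30, gc_target=0.5077, seed=seed))
            assert abs(g.gc_fraction - 0.5077) < 0.01

    def test_coding_fraction_within_two_points_of_target(self):
        g = synth.generate_genome(synth.GenomeSpec(
            length=40_000, n_genes=25, coding_fraction_target=0.85, seed=2))
        assert abs(g.coding_fraction - 0.85) < 0.02

    def test_genes_are_valid_nonoverlapping_cds(self, small_genome):
        from Bio.Seq import Seq

        from mutaccum.spectrum import revcomp

        for a, b in zip(small_genome.genes, small_genome.genes[1:]):
            assert b.start > a.end
        strands = {g.strand for g in small_genome.genes}
        assert strands == {"+", "-"}        # both strands exercised
        for gene in small_genome.genes:
            cds = small_genome.sequence[gene.start - 1 : gene.end]
            if gene.strand == "-":
                cds = revcomp(cds)
            prot = str(Seq(cds).translate(table=11))
            assert cds[:3] == "ATG"
            assert prot[-1] == "*" and "*" not in prot[:-1]

    def test_homopolymers_planted(self):
        g = synth.generate_genome(synth.GenomeSpec(
            length=20_000, n_genes=10, seed=3,
            homopolymer_spec=(("A", 7, 5), ("G", 6, 4))))
        assert g.sequence.count("A" * 7) >= 5
        assert g.sequence.count("G" * 6) >= 4

    def test_deterministic_output_bytes(self, tmp_path):
        from mutaccum import io_formats as io

        spec = synth.GenomeSpec(length=15_000, n_genes=8, seed=11)
        paths = []
        for tag in ("a", "b"):
            g = synth.generate_genome(spec)
            fa, gff = tmp_path / f"{tag}.fa", tmp_path / f"{tag}.gff"
            io.write_reference(g, fa, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="infeasible|tile"):
            synth.generate_genome(synth.GenomeSpec(
                length=100, coding_fraction_target=1.0, n_genes=16, seed=0))

    def test_impossible_homopolymer_request_rejected(self):
        with pytest.raises(ValueError, match="homopolymer"):
            synth.generate_genome(synth.GenomeSpec(
                length=3_000, coding_fraction_target=0.99, n_genes=2, seed=0,
                homopolymer_spec=(("A", 50, 100),)))


class TestSimulateMALines:
    def test_zero_rates_give_zero_mutations(self, small_genome):
        design = synth.ExperimentDesign(
            groups={"37C": synth.GroupDesign(3, 24.0, 37.0, 1)}, seed=1)
        exp = synth.simulate_ma_lines(small_genome, synth.RateSpec(), design)
        assert all(len(v) == 0 for v in exp.calls.values())

    def test_poisson_mean_matches_rate_times_sites_times_generations(self):
        """Single class at 1e-7/nt/gen on ~1e6 eligible sites for 810
        generations: sample mean within 3 SE of lambda."""
        g = synth.generate_genome(synth.GenomeSpec(length=100_000, n_genes=0, seed=4))
        n_at = sum(g.sequence.count(b) for b in "AT")
        rate = 1e-6
        lam = rate * n_at * 810.0
        design = synth.ExperimentDesign(
            groups={"37C": synth.GroupDesign(200, 24.0, 37.0, 1)},
            colony_cells_cv=0.0, seed=6)
        exp = synth.simulate_ma_lines(
            g, synth.RateSpec(six_type={"A:T>G:C": rate}), design)
        counts = [len(v) for v in exp.calls.values()]
        se = math.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_unbiased_placement_matches_eligible_coding_fraction(self, small_genome):
        g = small_genome
        design = synth.ExperimentDesign(
            groups={"37C": synth.GroupDesign(30, 24.0, 37.0, 1)}, seed=8)
        rate = 6e-6
        exp = synth.simulate_ma_lines(
            g, synth.RateSpec(six_type={"G:C>A:T": rate}), design)
        calls = [c for line in exp.calls.values() for c in line]
        assert len(calls) > 2000
        coding = sum(1 for c in calls if g.coding_mask[c.position - 1])
        frac = coding / len(calls)
        eligible = [i for i, b in enumerate(g.sequence) if b in "GC"]
        p = float(np.mean([g.coding_mask[i] for i in eligible]))
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / len(calls))

    def test_positive_rate_with_no_eligible_sites_names_class(self):
        from mutaccum.io_formats import AnnotatedGenome

        g = AnnotatedGenome("at", "ATATATAT" * 10)
        design = synth.ExperimentDesign(
            groups={"37C": synth.GroupDesign(1, 24.0, 37.0, 1)}, seed=1)
        with pytest.raises(ValueError, match="G:C>C:G"):
            synth.simulate_ma_lines(
                g, synth.RateSpec(six_type={"G:C>C:G": 1e-8}), design)

    def test_deterministic_under_seed(self, small_genome, inflated_rates):
        design = synth.ExperimentDesign(
            groups={"25C": synth.GroupDesign(2, 72.0, 25.0, 1)}, seed=19)
        a = synth.simulate_ma_lines(small_genome, inflated_rates, design)
        b = synth.simulate_ma_lines(small_genome, inflated_rates, design)
        assert a.calls == b.calls
        assert a.true_generations == b.true_generations

    def test_depth_attached_around_design_mean(self, small_genome, inflated_rates):
        design = synth.ExperimentDesign(
            groups={"37C": synth.GroupDesign(4, 24.0, 37.0, 1)}, seed=2)
        exp = synth.simulate_ma_lines(small_genome, inflated_rates, design)
        depths = [c.depth for line in exp.calls.values() for c in line]
        assert len(depths) > 50
        assert abs(np.mean(depths) - 163.0) < 3 * math.sqrt(163.0 / len(depths))

    def test_spectrum_round_trip_recovers_input_proportions(self, small_genome):
        """Classifying simulated calls recovers the six-type mix within
        3 binomial SE at >= 1000 mutations."""
        g = small_genome
        rates = {t: r for t, r in zip(SIX_TYPES, (5e-6, 8e-6, 1e-6, 2e-6, 1e-6, 1e-6))}
        design = synth.ExperimentDesign(
            groups={"37C": synth.GroupDesign(12, 24.0, 37.0, 1)}, seed=23)
        exp = synth.simulate_ma_lines(g, synth.RateSpec(six_type=rates), design)
        calls = [c for line in exp.calls.values() for c in line]
        assert len(calls) >= 1000
        observed = {t: 0 for t in SIX_TYPES}
        for c in calls:
            observed[six_type_of(c.ref, c.alt)[0]] += 1
        # expected mix: rate_t * eligible sites of the matching pair
        n_at = sum(g.sequence.count(b) for b in "AT")
        n_gc = len(g) - n_at
        weights = {t: rates[t] * (n_at if t.startswith("A:T") else n_gc)
                   for t in SIX_TYPES}
        total_w = sum(weights.values())
        n = len(calls)
        for t in SIX_TYPES:
            p = weights[t] / total_w
            se = math.sqrt(p * (1 - p) / n)
            assert abs(observed[t] / n - p) < 3 * se + 1e-9, t

    def test_indels_concentrate_in_runs(self):
        g = synth.generate_genome(synth.GenomeSpec(
            length=30_000, n_genes=0, seed=31,
            homopolymer_spec=(("A", 8, 40), ("T", 8, 40))))
        from mutaccum.synthetic_data import _run_mask

        runs = _run_mask(g.sequence, 3)
        design = synth.ExperimentDesign(
            groups={"37C": synth.GroupDesign(20, 24.0, 37.0, 1)}, seed=32)
        spec = synth.RateSpec(indel={(1, "loss"): 5e-7}, in_run_multiplier=8.0)
        exp = synth.simulate_ma_lines(g, spec, design)
        calls = [c for line in exp.calls.values() for c in line]
        assert len(calls) > 300
        in_run = sum(1 for c in calls if runs[c.position - 1])
        expected = 8.0 * runs.sum() / ((~runs).sum() + 8.0 * runs.sum())
        frac = in_run / len(calls)
        se = math.sqrt(expected * (1 - expected) / len(calls))
        assert abs(frac - expected) < 4 * se

    def test_generation_truth_matches_estimator(self, small_genome):
        """Simulation truth G is exactly the window-weighted estimator."""
        design = synth.ExperimentDesign(
            groups={"25C": synth.GroupDesign(3, 72.0, 25.0, 1)}, seed=40)
        exp = synth.simulate_ma_lines(small_genome, synth.RateSpec(), design)
        for lid, rec in exp.records.items():
            assert exp.true_generations[lid] == rec.total_generations


class TestRateRecovery:
    def test_mutation_rate_estimator_recovers_truth(self, small_genome):
        """Known per-nt rate is recovered by m/(G*L) within the group CL."""
        from mutaccum import rates as rates_mod

        g = small_genome
        rate = 1e-6
        n_at = sum(g.sequence.count(b) for b in "AT")
        true_mu = rate * n_at / len(g)      # per genome nucleotide
        design = synth.ExperimentDesign(
            groups={"37C": synth.GroupDesign(20, 24.0, 37.0, 1)}, seed=55)
        exp = synth.simulate_ma_lines(
            g, synth.RateSpec(six_type={"A:T>G:C": rate}), design)
        per_line = [
            rates_mod.mutation_rate(
                len(exp.calls[lid]), exp.records[lid].total_generations, len(g))
            for lid in exp.calls
        ]
        est = rates_mod.rate_summary(per_line)
        lo, hi = est.ci
        assert lo <= true_mu <= hi
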