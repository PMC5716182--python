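"""Allele state machine, expression/selection logic, truncation prediction,
workflow simulation."""

import numpy as np
import pytest

from trapforge import alleles as al
from trapforge import fixtures as fx
from trapforge.errors import ConfigError, ConstructionError, ProtocolError
from trapforge.recombine import integrate_insertion_vector
from trapforge.seqmodel import Interval


class TestEndPhase:
    def _gene(self, cds_lengths):
        pos, exons, cds = 100, [], []
        for n in cds_lengths:
            exons.append(Interval(pos, pos + n))
            cds.append(Interval(pos, pos + n))
            pos += n + 500
        return al.GeneModel("g", "+", exons, cds)

    def test_multiple_of_three_is_phase_zero(self):
        gene = self._gene([60, 90])
        assert al.end_phase(gene, Interval(0, 10_000)) == 0

    def test_one_extra_nucleotide_is_phase_one(self):
        gene = self._gene([60, 91])
        assert al.end_phase(gene, Interval(0, 10_000)) == 1

    def test_partial_homology_uses_most_3prime_contained_exon(self):
        gene = self._gene([60, 91, 33])
        # homology ends before the third exon: phase from exons 1-2 only
        assert al.end_phase(gene, Interval(0, 800)) == 1

    @pytest.mark.parametrize("seed,phase", [(100, 0), (101, 1), (102, 2)])
    def test_fixture_phase_target_honoured(self, seed, phase):
        gene, _ = fx.make_gene_locus(seed=seed, phase_target=phase)
        hom = Interval(gene.landmarks["g5"], gene.landmarks["g3"])
        assert al.end_phase(gene, hom) == phase


class TestStateMachine:
    def test_transition_table(self, reference_alleles):
        assert reference_alleles["tm1a"].state == "tm1a"
        assert al.apply_recombinase(reference_alleles["tm1a"], "Flp").state == "tm1c"
        assert al.apply_recombinase(reference_alleles["tm1a"], "Cre").state == "tm1b"
        assert al.apply_recombinase(reference_alleles["tm1c"], "Cre").state == "tm1d"

    def test_census_accepts_all_canonical_states(self, locus, reference_alleles):
        gene, _ = locus
        for allele in reference_alleles.values():
            al.validate_allele(allele, gene)

    def test_census_rejects_all_cross_state_mutations(self, locus, reference_alleles):
        """Every allele relabelled with each of the five wrong states must
        fail the census: 6 x 5 = 30 rejections."""
        gene, _ = locus
        rejected = 0
        for state, allele in reference_alleles.items():
            for wrong in set(al.ALLELE_STATES) - {state}:
                fake = al.AlleleMap(allele.seq, wrong)
                with pytest.raises(ConstructionError):
                    al.validate_allele(fake, gene)
                rejected += 1
        assert rejected == 30

    def test_recombinase_without_sites_is_identity(self, reference_alleles):
        wt = reference_alleles["wt"]
        assert al.apply_recombinase(wt, "Cre") is wt

    def test_unknown_enzyme(self, reference_alleles):
        with pytest.raises(ConfigError):
            al.apply_recombinase(reference_alleles["tm1a"], "Dre")


class TestExpressionOutcome:
    def test_state_outcomes(self, locus, reference_alleles):
        gene, _ = locus
        expect = {
            "wt": (True, set()),
            "tm1a": (False, {"lacZ", "neo"}),
            "tm1b": (False, {"lacZ", "neo"}),
            "tm1c": (True, set()),
            "tm1d": (False, set()),
            "tm2": (False, {"hygro", "GFP"}),
        }
        for state, (full, markers) in expect.items():
            out = al.expression_outcome(reference_alleles[state], gene)
            assert out["full_protein"] is full, state
            assert out["markers_expressed"] == markers, state

    def test_cis_integration_into_tm1a_silences_hygro(self, locus, vector,
                                                      reference_alleles):
        gene, _ = locus
        cis = al.AlleleMap(
            integrate_insertion_vector(reference_alleles["tm1a"].seq, vector),
            "tm1a")
        out = al.expression_outcome(cis, gene)
        assert "hygro" not in out["markers_expressed"]
        assert out["markers_expressed"] == {"lacZ", "neo"}

    def test_low_expression_silences_traps(self, vector):
        gene, genome = fx.make_gene_locus(seed=31, phase_target=1,
                                          expression_pct_trfr=0.5)
        tm1a = al.build_tm1a(gene, genome)
        assert al.expression_outcome(tm1a, gene)["markers_expressed"] == set()

    def test_mismatched_frame_silences_hygro(self, locus):
        gene, genome = locus   # end phase 1
        from trapforge import parts
        bad = fx.build_fixture_vector(gene, genome, seed=7,
                                      force_cassette=parts.hyg_gfp_cassette(2))
        tm2 = al.AlleleMap(
            integrate_insertion_vector(
                al.wild_type_allele(gene, genome).seq, bad["vector"]), "tm2")
        assert al.expression_outcome(tm2, gene)["markers_expressed"] == set()


class TestTruncation:
    def test_printed_residue_counts_give_printed_masses(self):
        # Setdb1-class and Jarid2-class truncations
        assert al.mass_kda(353) == 39
        assert al.mass_kda(97) == 11

    def test_trap_truncation_equals_upstream_coding_over_three(self, locus,
                                                               reference_alleles):
        gene, _ = locus
        up = sum(c.length() for c in gene.cds[:2])  # exons 1-2 precede the trap
        out = al.predict_truncation(reference_alleles["tm1a"], gene)
        assert out["aa_length"] == up // 3

    def test_tm2_truncation_spans_homology_exons(self, locus, reference_alleles):
        gene, _ = locus
        up = sum(c.length() for c in gene.cds[:4])  # exons 1-4 precede the trap
        out = al.predict_truncation(reference_alleles["tm2"], gene)
        assert out["aa_length"] == up // 3

    def test_frameshift_readthrough_shorter_than_full_protein(self, locus,
                                                              reference_alleles):
        gene, _ = locus
        full = sum(c.length() for c in gene.cds) // 3 - 1
        out = al.predict_truncation(reference_alleles["tm1d"], gene)
        up = sum(c.length() for c in gene.cds[:2]) // 3
        assert up <= out["aa_length"] < full


class TestTargetingStep:
    def test_het_nonessential_recovers_only_trans_biallelic(self, locus, vector):
        gene, genome = locus
        line = fx.make_cell_line(gene, genome, ("tm1a", "wt"), seed=1)
        res = al.simulate_targeting_step(line, vector, "hygromycin")
        assert res["recoverable_genotypes"] == ["tm1a/tm2"]
        cis = next(o for o in res["outcomes"] if o["target"] == "allele_a")
        assert not cis["marker_expressed"]

    def test_essential_gene_yields_nothing(self):
        gene, genome = fx.make_gene_locus(seed=8, phase_target=0, essential=True)
        vec = fx.build_fixture_vector(gene, genome, seed=8)["vector"]
        line = fx.make_cell_line(gene, genome, ("tm1a", "wt"), seed=1)
        res = al.simulate_targeting_step(line, vec)
        assert res["recoverable_genotypes"] == []
        # the same vector readily targets wild-type cells
        wt_line = fx.make_cell_line(gene, genome, ("wt", "wt"), seed=1)
        assert al.simulate_targeting_step(wt_line, vec)["recoverable_genotypes"] \
            == ["tm2/+"]

    def test_random_integration_never_recovered(self, locus, vector):
        gene, genome = locus
        line = fx.make_cell_line(gene, genome, ("wt", "wt"), seed=1)
        res = al.simulate_targeting_step(line, vector)
        rand = next(o for o in res["outcomes"] if o["class"] == "random")
        assert not rand["recoverable"]

    def test_unknown_drug(self, locus, vector):
        gene, genome = locus
        line = fx.make_cell_line(gene, genome, ("wt", "wt"), seed=1)
        with pytest.raises(ConfigError):
            al.simulate_targeting_step(line, vector, "blasticidin")


def _route(vector):
    return ["flp", {"electroporate": vector}, ("select", "hygromycin"),
            "screen_trans", "knockin_creert2", ("induce_4oht", 48)]


class TestProtocol:
    def test_inducible_conditional_route(self, locus, vector):
        gene, genome = locus
        line = fx.make_cell_line(gene, genome, ("tm1a", "wt"), seed=5,
                                 escaper_rate=1e-3)
        res = al.simulate_protocol(_route(vector), line, n_cells=100_000)
        final = res["final_population"]
        assert max(final, key=final.get) == "tm1d/tm2"
        assert 0 <= res["escaper_fraction"] < 0.01

    @pytest.mark.parametrize("rate", [1e-2, 1e-3])
    def test_escaper_rate_recovered_within_three_sd(self, locus, vector, rate):
        gene, genome = locus
        n = 100_000
        line = fx.make_cell_line(gene, genome, ("tm1a", "wt"), seed=9,
                                 escaper_rate=rate)
        res = al.simulate_protocol(_route(vector), line, n_cells=n)
        sd = np.sqrt(rate * (1 - rate) / n)
        assert abs(res["escaper_fraction"] - rate) <= 3 * sd

    def test_zero_leak_means_no_premature_conversion(self, locus, vector):
        gene, genome = locus
        line = fx.make_cell_line(gene, genome, ("tm1a", "wt"), seed=5,
                                 leak_rate=0.0)
        steps = ["flp", {"electroporate": vector}, ("select", "hygromycin"),
                 "screen_trans", "knockin_creert2"]
        res = al.simulate_protocol(steps, line)
        assert all("tm1d" not in g for g in res["final_population"])

    def test_leak_converts_uninduced_cells(self, locus, vector):
        gene, genome = locus
        line = fx.make_cell_line(gene, genome, ("tm1a", "wt"), seed=5,
                                 leak_rate=0.05)
        steps = ["flp", {"electroporate": vector}, ("select", "hygromycin"),
                 "screen_trans", "knockin_creert2"]
        res = al.simulate_protocol(steps, line, n_cells=100_000)
        assert any("tm1d" in g for g in res["final_population"])

    def test_induction_without_creert2_is_an_error(self, locus, vector):
        gene, genome = locus
        line = fx.make_cell_line(gene, genome, ("tm1c", "wt"), seed=5)
        with pytest.raises(ProtocolError):
            al.simulate_protocol([("induce_4oht", 48)], line)


class TestCellLineFactory:
    def test_genotype_strings(self, locus):
        gene, genome = locus
        assert fx.make_cell_line(gene, genome, ("tm1a", "wt")).genotype == "tm1a/+"
        assert fx.make_cell_line(gene, genome, ("wt", "wt")).genotype == "+/+"

    def test_induction_ready_line(self, locus, vector):
        gene, genome = locus
        line = fx.make_cell_line(gene, genome, ("tm1c", "tm2"),
                                 transgenes={"CreERT2"}, vector=vector)
        assert line.genotype == "tm1c/tm2"
        assert "CreERT2" in line.transgenes

    def test_unreachable_pair_rejected(self, locus):
        gene, genome = locus
        with pytest.raises(ConstructionError):
            fx.make_cell_line(gene, genome, ("tm1d", "tm1d"))
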