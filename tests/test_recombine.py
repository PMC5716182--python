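"""Recombination engine: Gateway exchange, Cre/Flp, linearization,
insertion targeting with gap repair, random integration."""

import pytest

from trapforge import alleles as al
from trapforge import fixtures as fx
from trapforge import parts
from trapforge.errors import (
    AmbiguousSiteError,
    MissingSiteError,
    MultipleSiteError,
    MustLinearizeError,
    NoIntegrationError,
    NoSiteError,
    OrientationError,
)
from trapforge.recombine import (
    gateway_three_way,
    integrate_insertion_vector,
    linearize,
    random_integrate,
    ssr_excise,
)
from trapforge.seqmodel import AnnotatedSequence, Feature, Interval, scan_motif


@pytest.fixture(scope="module")
def gateway_inputs(locus):
    gene, genome = locus
    spec = fx.make_intermediate_vector(gene, genome, seed=7)
    return (spec.plasmid, fx.make_adaptor(),
            fx.make_trap_donor(parts.hyg_gfp_cassette(1)))


class TestGateway:
    def test_length_bookkeeping(self, gateway_inputs):
        intermediate, adaptor, trap = gateway_inputs
        res = gateway_three_way(intermediate, adaptor, trap)
        r1 = intermediate.find(subtype="attR1")[0]
        r2 = intermediate.find(subtype="attR2")[0]
        r3 = intermediate.find(subtype="attR3")[0]
        r4 = intermediate.find(subtype="attR4")[0]
        displaced_stuffer = r2.start - r1.end
        displaced_backbone = r4.start - r3.end
        l1 = adaptor.find(subtype="attL1")[0]
        l2 = adaptor.find(subtype="attL2")[0]
        pay12 = l2.start - l1.end
        l3 = trap.find(subtype="attL3")[0]
        l4 = trap.find(subtype="attL4")[0]
        pay34 = l4.start - l3.end
        expected = (len(intermediate) - displaced_stuffer
                    - displaced_backbone + pay12 + pay34)
        assert len(res["product"]) == expected

    def test_product_feature_census(self, gateway_inputs):
        res = gateway_three_way(*gateway_inputs)
        product = res["product"]
        assert len(scan_motif(product, parts.PMEI_SITE, both_strands=True)) == 1
        assert len(product.find(subtype="loxP")) == 2  # adaptor + distal
        assert len(product.find(kind="cassette", marker="hygro-GFP")) == 1
        for st in ("attR1", "attR2", "attR3", "attR4",
                   "attL1", "attL2", "attL3", "attL4"):
            assert not product.find(subtype=st)
        for i in "1234":
            assert len(product.find(subtype=f"attB{i}")) == 1

    def test_byproducts_carry_displaced_segments(self, gateway_inputs):
        res = gateway_three_way(*gateway_inputs)
        labels = {f.label for b in res["byproducts"] for f in b.features}
        assert "stuffer" in labels        # displaced exchange-region stuffer
        assert "zeo" in labels            # displaced acceptor backbone marker

    def test_missing_site_is_named(self, gateway_inputs):
        intermediate, adaptor, trap = gateway_inputs
        broken = adaptor.copy()
        broken.features = [f for f in broken.features
                           if f.qualifiers.get("site_subtype") != "attL2"]
        with pytest.raises(MissingSiteError, match="attL2"):
            gateway_three_way(intermediate, broken, trap)


def _linear_with_sites(subtype, positions, strands=("+", "+")):
    site = {"loxP": parts.LOXP, "FRT": parts.FRT}[subtype]
    residues = list("A" * 1000)
    feats = []
    for pos, strand in zip(positions, strands):
        residues[pos:pos + 34] = list(site)
        feats.append(Feature(subtype, "recomb_site",
                             Interval(pos, pos + 34, strand),
                             {"site_subtype": subtype}))
    return AnnotatedSequence("".join(residues), features=feats)


class TestSsrExcise:
    def test_intersite_spacing_removed_one_site_kept(self):
        seq = _linear_with_sites("loxP", [100, 500])
        res = ssr_excise(seq, "loxP")
        assert len(res["main"]) == 1000 - 400
        assert len(res["main"].find(subtype="loxP")) == 1
        assert len(res["main"]) + len(res["excised_circle"]) == 1000

    def test_flp_on_tm1a_gives_tm1c_census(self, locus):
        gene, genome = locus
        tm1a = al.build_tm1a(gene, genome)
        res = ssr_excise(tm1a.seq, "FRT")
        main = res["main"]
        assert not main.find(kind="cassette", marker="beta-geo")
        assert len(main.find(subtype="FRT")) == 1
        assert len(main.find(subtype="loxP")) == 2

    def test_no_site_is_identity_with_warning(self, caplog):
        seq = _linear_with_sites("loxP", [100, 500])
        res = ssr_excise(seq, "FRT")
        assert res["excised_circle"] is None
        assert res["main"].residues == seq.residues

    def test_idempotent_once_one_site_remains(self):
        seq = _linear_with_sites("loxP", [100, 500])
        once = ssr_excise(seq, "loxP")["main"]
        twice = ssr_excise(once, "loxP")["main"]
        assert twice.residues == once.residues

    def test_three_sites_ambiguous(self):
        seq = _linear_with_sites("loxP", [100, 400, 700],
                                 strands=("+", "+", "+"))
        with pytest.raises(AmbiguousSiteError):
            ssr_excise(seq, "loxP")

    def test_inverted_repeats_unsupported(self):
        seq = _linear_with_sites("loxP", [100, 500], strands=("+", "-"))
        with pytest.raises(OrientationError):
            ssr_excise(seq, "loxP")


class TestLinearize:
    def _plasmid(self, n_sites):
        residues = list("ACGT" * 500)
        feats = []
        for i in range(n_sites):
            pos = 100 + 600 * i
            residues[pos:pos + 8] = list(parts.PMEI_SITE)
        return AnnotatedSequence("".join(residues), "circular", feats)

    def test_length_conserved_and_cut_mid_site(self):
        plasmid = self._plasmid(1)
        lin = linearize(plasmid)
        assert len(lin) == len(plasmid) and lin.topology == "linear"
        # blunt cut GTTT/AAAC: the opened molecule starts with AAAC
        assert lin.residues.startswith("AAAC")
        assert lin.residues.endswith("GTTT")

    def test_two_sites_cannot_linearize_intact(self):
        with pytest.raises(MultipleSiteError):
            linearize(self._plasmid(2))

    def test_no_site(self):
        with pytest.raises(NoSiteError):
            linearize(self._plasmid(0))


class TestIntegration:
    def test_gap_repair_length_identity_and_ex5_duplication(self, locus, vector):
        gene, genome = locus
        wt = al.wild_type_allele(gene, genome)
        product = integrate_insertion_vector(wt.seq, vector)
        gap = gene.landmarks["d5"] - gene.landmarks["u3"]
        assert len(product) == len(genome) + len(vector) + gap
        assert len(product.find(kind="primer_site", label="ex5")) == 2

    def test_cassette_strictly_between_homology_copies(self, locus, vector):
        gene, genome = locus
        wt = al.wild_type_allele(gene, genome)
        product = integrate_insertion_vector(wt.seq, vector)
        cassette = product.find(kind="cassette", marker="hygro-GFP")[0]
        arms = product.find(kind="homology_arm")
        ex5_sites = product.find(kind="primer_site", label="ex5")
        assert ex5_sites[0].end < cassette.start < cassette.end < ex5_sites[1].start
        assert any(a.end <= cassette.start for a in arms)

    def test_mismatched_arm_refused(self, locus, vector):
        gene, genome = locus
        mutated = genome.residues[:3000] + "N" * 50 + genome.residues[3050:]
        allele = AnnotatedSequence(mutated, features=list(genome.features))
        with pytest.raises(NoIntegrationError):
            integrate_insertion_vector(allele, vector)

    def test_circular_vector_refused(self, locus, vector):
        gene, genome = locus
        circ = AnnotatedSequence(vector.residues, "circular", vector.features)
        with pytest.raises(MustLinearizeError):
            integrate_insertion_vector(genome, circ)


class TestRandomIntegrate:
    def test_deterministic_and_conserving(self, locus, vector):
        _, genome = locus
        p1 = random_integrate(genome, vector, seed=5)
        p2 = random_integrate(genome, vector, seed=5)
        assert p1.residues == p2.residues
        assert len(p1) == len(genome) + len(vector)

    def test_inserted_copy_lacks_gap_region(self, locus, vector):
        gene, genome = locus
        clone = fx.make_random_integration_clone(gene, genome, vector, seed=5)
        assert not clone["off_target"].find(kind="primer_site", label="ex5")
        total_ex5 = sum(len(c.find(kind="primer_site", label="ex5"))
                        for c in clone.values())
        assert total_ex5 == 1  # the intact chromosomal copy only


class TestRecombinaseAlgebra:
    @pytest.mark.parametrize("seed", range(10))
    def test_cre_flp_commute_to_tm1d(self, seed):
        gene, genome = fx.make_gene_locus(seed=seed)
        tm1a = al.build_tm1a(gene, genome)
        via_c = al.apply_recombinase(al.apply_recombinase(tm1a, "Flp"), "Cre")
        via_b = al.apply_recombinase(al.apply_recombinase(tm1a, "Cre"), "Flp")
        assert via_c.state == via_b.state == "tm1d"
        assert via_c.seq.residues == via_b.seq.residues
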