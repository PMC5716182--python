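import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from trapforge import alleles as al
from trapforge import fixtures as fx
from trapforge import genotyping as gt
from trapforge.recombine import integrate_insertion_vector


@pytest.fixture(scope="session")
def locus():
    """Default fixture locus: expressed, non-essential, end phase 1."""
    gene, genome = fx.make_gene_locus(seed=7, phase_target=1)
    return gene, genome


@pytest.fixture(scope="session")
def vector(locus):
    gene, genome = locus
    return fx.build_fixture_vector(gene, genome, seed=7)["vector"]


@pytest.fixture(scope="session")
def reference_alleles(locus, vector):
    """One validated AlleleMap per workflow state on the default locus."""
    gene, genome = locus
    wt = al.wild_type_allele(gene, genome)
    tm1a = al.build_tm1a(gene, genome)
    tm1b = al.apply_recombinase(tm1a, "Cre")
    tm1c = al.apply_recombinase(tm1a, "Flp")
    tm1d = al.apply_recombinase(tm1c, "Cre")
    tm2 = al.AlleleMap(integrate_insertion_vector(wt.seq, vector), "tm2")
    return {"wt": wt, "tm1a": tm1a, "tm1b": tm1b, "tm1c": tm1c,
            "tm1d": tm1d, "tm2": tm2}


@pytest.fixture(scope="session")
def panel(locus, vector, reference_alleles):
    gene, _ = locus
    refs = {k: v for k, v in reference_alleles.items() if k != "tm1b"}
    return gt.design_panel(gene, refs, vector)
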