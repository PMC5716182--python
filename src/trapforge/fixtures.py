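"""Seeded synthetic-data generators: gene loci, Intermediate Vectors,
adaptor/trap donors, cell lines and screening tables with known truth.

A generated locus is a multi-exon expressed gene laid out the way the
targeted-trapping method expects its substrates: a promoter-bearing first
exon outside the homology region, a critical exon (length not divisible by
3, so its deletion frameshifts) inside the loxP-flankable region, coding
exons inside both homology arms, an external gf3 primer site upstream of
the 5' arm and the ex5 site inside the gap region.  Default arm and
cassette sizes are calibrated so the genotyping amplicons land in the
published size classes (~12 kb tm1a and ~7 kb tm1c for gf3/LR, 6-7 kb for
ex5/hygro_1R, ~6 kb for the cis junction).

All generators are deterministic per seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import parts
from .alleles import (
    AlleleMap,
    CellLine,
    GeneModel,
    apply_recombinase,
    build_tm1a,
    wild_type_allele,
)
from .errors import ConstructionError, GenerationError, GeometryError
from .recombine import integrate_insertion_vector
from .seqmodel import AnnotatedSequence, Feature, Interval, concat
from .vectorbuild import IntermediateVectorSpec

STOPS = parts.STOP_CODONS

# locus geometry defaults (nt); see docs/methods.md for the calibration
FLANK5 = 800
PROMOTER_LEN = 30
EXON1_LEN = 200
UTR5_LEN = 50
GF3_OFFSET = 1130          # gf3 primer site start
G5 = 2150
EXON2_START = 3500
U3 = 7150
EX5_OFFSET = 7450          # ex5 primer site start (inside the gap region)
CE_START = 7550
D5 = 7950
EXON4_START = 9000
EXON4_LEN = 210
G3 = 12750
EXON5_START = 13100
EXON5_LEN = 400
FLANK3 = 800


def _coding_sequence(rng: np.random.Generator, n_nt: int) -> str:
    """Codon string stop-free in frame 0 with stops in frames +1/+2 and no
    PmeI site on either strand."""
    assert n_nt % 3 == 0
    for _ in range(50):
        s = "".join(rng.choice(parts._CODONS, size=n_nt // 3))
        ok_shift = all(any(s[i:i + 3] in STOPS for i in range(off, n_nt - 2, 3))
                       for off in (1, 2))
        if ok_shift and parts.PMEI_SITE not in s and \
                parts.PMEI_SITE not in parts.revcomp(s):
            return s
    raise GenerationError("could not generate a frame-0-only coding sequence")


def make_gene_locus(seed: int, n_exons: int = 5,
                    phase_target: int | None = None,
                    expression_pct_trfr: float = 100.0,
                    essential: bool = False,
                    extra_pmei: int = 0) -> tuple[GeneModel, AnnotatedSequence]:
    """Generate a synthetic expressed locus plus its gene model.

    ``phase_target`` fixes the end phase of the most 3' exon inside the
    default homology region (exon 4) by adjusting the exon-2 length;
    ``extra_pmei`` plants that many PmeI sites inside the 3' homology arm
    (making the locus unsuitable for intact linearization).
    """
    if n_exons != 5:
        raise GenerationError("the default fixture geometry uses 5 exons")
    for attempt in range(20):
        try:
            return _make_gene_locus(seed, attempt, phase_target,
                                    expression_pct_trfr, essential, extra_pmei)
        except GenerationError:
            continue
    raise GenerationError(f"locus generation failed for seed {seed}")


def _make_gene_locus(seed: int, attempt: int, phase_target,
                     expression_pct_trfr, essential,
                     extra_pmei) -> tuple[GeneModel, AnnotatedSequence]:
    rng = np.random.default_rng([seed, attempt])
    phase = int(rng.integers(0, 3)) if phase_target is None else int(phase_target)
    if phase not in (0, 1, 2):
        raise GenerationError(f"phase_target must be 0/1/2, got {phase}")

    ce_len = 151 if rng.integers(0, 2) == 0 else 152   # never divisible by 3
    # cumulative CDS through exon 4 must be == phase (mod 3)
    e1_cds = EXON1_LEN - UTR5_LEN                      # 150, == 0 mod 3
    base = e1_cds + ce_len + EXON4_LEN
    e2_len = 180 + (phase - base - 180) % 3
    e5_cds = 240 + (3 - (base + e2_len + 240) % 3) % 3
    total_cds = base + e2_len + e5_cds
    assert total_cds % 3 == 0
    cds = _coding_sequence(rng, total_cds - 3) + "TAA"

    off = 0
    def take(n: int) -> str:
        nonlocal off
        s = cds[off:off + n]
        off += n
        return s

    exon_seqs = {
        1: parts.random_dna(rng, UTR5_LEN) + take(e1_cds),
        2: take(e2_len),
        3: take(ce_len),
        4: take(EXON4_LEN),
        5: take(e5_cds) + parts.random_dna(rng, EXON5_LEN - e5_cds),
    }
    if len(exon_seqs[5]) != EXON5_LEN:
        raise GenerationError("exon 5 sizing error")

    coords = {
        "promoter": (FLANK5, FLANK5 + PROMOTER_LEN),
        "exon1": (FLANK5 + PROMOTER_LEN, FLANK5 + PROMOTER_LEN + EXON1_LEN),
        "exon2": (EXON2_START, EXON2_START + e2_len),
        "exon3": (CE_START, CE_START + ce_len),
        "exon4": (EXON4_START, EXON4_START + EXON4_LEN),
        "exon5": (EXON5_START, EXON5_START + EXON5_LEN),
    }
    length = EXON5_START + EXON5_LEN + FLANK3
    seq = np.array(list(parts.random_dna(rng, length)))

    def paste(start: int, s: str):
        seq[start:start + len(s)] = list(s)

    for i in range(1, 6):
        paste(coords[f"exon{i}"][0], exon_seqs[i])
    gf3 = parts.random_dna(rng, 20)
    ex5 = parts.random_dna(rng, 20)
    paste(GF3_OFFSET, gf3)
    paste(EX5_OFFSET, ex5)
    pmei_positions = []
    if extra_pmei:
        lo, hi = EXON4_START + EXON4_LEN + 100, G3 - 100
        pos = sorted(rng.choice(np.arange(lo, hi, 50), size=extra_pmei,
                                replace=False))
        for p in pos:
            paste(int(p), parts.PMEI_SITE)
            pmei_positions.append(int(p))
    residues = "".join(seq)
    # planting must not create accidental extra sites
    n_sites = residues.count(parts.PMEI_SITE)
    if n_sites != extra_pmei:
        raise GenerationError("PmeI planting failed")

    feats = [Feature("promoter", "promoter", Interval(*coords["promoter"]))]
    cds_bounds = {
        "exon1": (coords["exon1"][0] + UTR5_LEN, coords["exon1"][1]),
        "exon2": coords["exon2"],
        "exon3": coords["exon3"],
        "exon4": coords["exon4"],
        "exon5": (coords["exon5"][0], coords["exon5"][0] + e5_cds),
    }
    for i in range(1, 6):
        feats.append(Feature(f"exon{i}", "exon", Interval(*coords[f"exon{i}"])))
        feats.append(Feature(f"cds{i}", "cds_segment", Interval(*cds_bounds[f"exon{i}"])))
    feats.append(Feature("critical_exon", "critical_exon", Interval(*coords["exon3"])))
    feats.append(Feature("gf3", "primer_site", Interval(GF3_OFFSET, GF3_OFFSET + 20)))
    feats.append(Feature("ex5", "primer_site", Interval(EX5_OFFSET, EX5_OFFSET + 20)))
    genome = AnnotatedSequence(residues, "linear", feats, id=f"locus_{seed}")

    gene = GeneModel(
        gene_id=f"Gene{seed}", strand="+",
        exons=[Interval(*coords[f"exon{i}"]) for i in range(1, 6)],
        cds=[Interval(*cds_bounds[f"exon{i}"]) for i in range(1, 6)],
        expression_pct_trfr=expression_pct_trfr,
        essential_in_es=essential,
        critical_exon_index=2,
        landmarks={"g5": G5, "u3": U3, "d5": D5, "g3": G3,
                   "gf3": GF3_OFFSET, "ex5": EX5_OFFSET,
                   "phase": phase, "extra_pmei": pmei_positions},
    )
    return gene, genome


def _att(subtype: str) -> AnnotatedSequence:
    core = parts.ATT_CORES[int(subtype[-1])]
    s = AnnotatedSequence(core, id=subtype)
    s.add_feature(parts.site_feature(subtype, 0))
    return s


def _marker(name: str) -> AnnotatedSequence:
    orf = parts.MARKER_ORFS[name]
    s = AnnotatedSequence(orf, id=name)
    s.add_feature(Feature(name, "marker", Interval(0, len(orf)),
                          {"marker_name": name}))
    return s


def _origin() -> AnnotatedSequence:
    s = AnnotatedSequence(parts.ORIGIN, id="ori")
    s.add_feature(Feature("ori", "origin", Interval(0, len(parts.ORIGIN))))
    return s


def _loxp() -> AnnotatedSequence:
    s = AnnotatedSequence(parts.LOXP, id="loxP")
    s.add_feature(parts.site_feature("loxP", 0))
    return s


def _plain(rng: np.random.Generator, n: int, id: str = "spacer") -> AnnotatedSequence:
    s = AnnotatedSequence(parts.random_dna(rng, n), id=id)
    s.add_feature(Feature(id, "cassette", Interval(0, n), {"marker_name": id}))
    return s


def make_intermediate_vector(gene: GeneModel, genome: AnnotatedSequence,
                             seed: int = 0) -> IntermediateVectorSpec:
    """Assemble an IKMC-style Intermediate Vector for a fixture locus.

    Circular layout: 5' arm (G5..U3) | attR1 | stuffer | attR2 |
    critical-exon region (U3..D5) | rpsL | loxP | 3' arm (D5..G3) | attR3 |
    backbone (ori, zeo, amp) | attR4.
    """
    lm = gene.landmarks
    g5, u3, d5, g3 = lm["g5"], lm["u3"], lm["d5"], lm["g3"]
    if not (0 < g5 < u3 < d5 < g3 <= len(genome)):
        raise GeometryError(f"{gene.gene_id}: arm landmarks out of order")
    ce = gene.critical_exon
    if not (u3 < ce.start and ce.end < d5):
        raise GeometryError(f"{gene.gene_id}: critical exon not inside (U3, D5)")
    rng = np.random.default_rng(seed + 1_000_003)

    arm5 = genome.slice(g5, u3, id="arm5")
    arm5.add_feature(Feature("arm5", "homology_arm", Interval(0, len(arm5))))
    arm3 = genome.slice(d5, g3, id="arm3")
    arm3.add_feature(Feature("arm3", "homology_arm", Interval(0, len(arm3))))
    crit = genome.slice(u3, d5, id="critical_region")

    plasmid = concat(
        [arm5, _att("attR1"), _plain(rng, 600, "stuffer"), _att("attR2"),
         crit, _marker("rpsL"), _loxp(), arm3,
         _att("attR3"), _origin(), _marker("zeo"), _marker("amp"),
         _plain(rng, 1600, "backbone_pad"), _att("attR4")],
        id=f"IV_{gene.gene_id}", topology="circular")

    spec = IntermediateVectorSpec(
        gene_id=gene.gene_id,
        arm5=Interval(g5, u3), critical_region=Interval(u3, d5),
        arm3=Interval(d5, g3), plasmid=plasmid,
        meta={"design": "promoterless", "seed": seed})
    spec.qc_size()
    return spec


def make_adaptor() -> AnnotatedSequence:
    """The PmeI/loxP adaptor donor (pL1L2_RloxP-style): attL1 | PmeI site |
    spacer | loxP | attL2 | backbone (ori, nat)."""
    rng = np.random.default_rng(33_550_336)
    pmei = AnnotatedSequence(parts.PMEI_SITE, id="PmeI")
    pmei.add_feature(parts.site_feature("PmeI", 0))
    return concat(
        [_att("attL1"), pmei, _plain(rng, 300, "adaptor_spacer"), _loxp(),
         _att("attL2"), _origin(), _marker("nat")],
        id="pL1L2_RloxP", topology="circular")


def make_trap_donor(cassette: AnnotatedSequence) -> AnnotatedSequence:
    """A reading-frame variant of the hygromycin-GFP trap as a Gateway
    donor (pL3L4-style): attL3 | cassette | kan | ori | attL4 | backbone
    (cat marker)."""
    rng = np.random.default_rng(8_675_309)
    return concat(
        [_att("attL3"), cassette.copy(), _marker("kan"), _origin(),
         _att("attL4"), _marker("cat"), _plain(rng, 400, "donor_pad")],
        id=f"pL3L4_{cassette.id}", topology="circular")


def build_fixture_vector(gene: GeneModel, genome: AnnotatedSequence,
                         seed: int = 0,
                         force_cassette: AnnotatedSequence | None = None) -> dict:
    """Convenience: locus -> Intermediate Vector -> linearized pI_hygGFP.

    ``force_cassette`` overrides frame selection (every library slot maps to
    the given variant) — used to validate the frame rule by deliberately
    mis-framing the trap.
    """
    from .vectorbuild import build_pI_hygGFP

    spec = make_intermediate_vector(gene, genome, seed=seed)
    library = parts.cassette_library() if force_cassette is None else \
        {p: force_cassette for p in (0, 1, 2)}
    return build_pI_hygGFP(spec, make_adaptor(), library,
                           gene, genome) | {"spec": spec}


_LINEAGE = {"tm1a", "tm1b", "tm1c", "tm1d"}

_ROUTES = {
    "wt": (), "tm1a": ("tm1a",), "tm1b": ("tm1a", "Cre"),
    "tm1c": ("tm1a", "Flp"), "tm1d": ("tm1a", "Flp", "Cre"),
}


def _make_allele(state: str, gene: GeneModel, genome: AnnotatedSequence,
                 vector: AnnotatedSequence | None) -> AlleleMap:
    if state == "tm2":
        if vector is None:
            raise ConstructionError("tm2 allele needs a pI_hygGFP vector")
        wt = wild_type_allele(gene, genome)
        product = integrate_insertion_vector(wt.seq, vector)
        return AlleleMap(product, "tm2", provenance=["pI_hygGFP"])
    allele = wild_type_allele(gene, genome)
    for step in _ROUTES[state]:
        allele = build_tm1a(gene, genome) if step == "tm1a" \
            else apply_recombinase(allele, step)
    return allele


def make_cell_line(gene: GeneModel, genome: AnnotatedSequence,
                   states: tuple[str, str],
                   transgenes: set | None = None,
                   leak_rate: float = 0.0, escaper_rate: float = 0.0,
                   seed: int = 0,
                   vector: AnnotatedSequence | None = None) -> CellLine:
    """Cell line with the requested allele-state pair.

    Only pairs reachable by the engineering routes in scope are allowed: at
    most one allele from the knockout-first lineage (tm1a/tm1b/tm1c/tm1d)
    and at most one insertion-trap (tm2) allele.
    """
    a, b = states
    for s in states:
        if s not in _ROUTES and s != "tm2":
            raise ConstructionError(f"unknown allele state {s!r}")
    if sum(s in _LINEAGE for s in states) > 1 or states.count("tm2") > 1:
        raise ConstructionError(f"allele pair {a}/{b} is not reachable in scope")
    if "tm2" in states and vector is None:
        vector = build_fixture_vector(gene, genome, seed=seed)["vector"]
    return CellLine(
        allele_a=_make_allele(a, gene, genome, vector),
        allele_b=_make_allele(b, gene, genome, vector),
        gene=gene, transgenes=set(transgenes or ()),
        leak_rate=leak_rate, escaper_rate=escaper_rate, seed=seed)


def make_random_integration_clone(gene: GeneModel, genome: AnnotatedSequence,
                                  vector: AnnotatedSequence,
                                  seed: int = 0) -> dict:
    """A clone where the vector integrated randomly: the target locus stays
    intact (wild type, one chromosomal ex5 site) and the vector sits
    end-joined at a seeded-random position of an unrelated genomic flank,
    without gap repair — so no chromosome carries ex5 next to the trap and
    the ex5/hygro_1R screen is PCR-negative.

    Returns ``{"locus": ..., "off_target": ...}`` (two chromosomes).
    """
    from .recombine import random_integrate

    rng = np.random.default_rng(seed + 77)
    flank = AnnotatedSequence(parts.random_dna(rng, 20_000), "linear", [],
                              id=f"offtarget_{seed}")
    return {"locus": wild_type_allele(gene, genome).seq,
            "off_target": random_integrate(flank, vector, seed)}


def make_screen_table(truth: list[dict], colonies_per_experiment: int = 24,
                      seed: int = 0) -> tuple[pd.DataFrame, list[dict]]:
    """Binomial screening tallies with ground truth.

    ``truth`` rows: {gene, p_target, essential}.  Each gene gets a
    wild-type control row and a heterozygous (tm1a/+) experimental row;
    essential genes yield zero positives in the heterozygous row.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in truth:
        p = float(t["p_target"])
        if not 0.0 <= p <= 1.0:
            raise GenerationError(f"p_target {p} outside [0,1]")
        n = colonies_per_experiment
        rows.append({"gene": t["gene"], "line_genotype": "+/+",
                     "colonies_screened": n,
                     "colonies_positive": int(rng.binomial(n, p))})
        het_pos = 0 if t.get("essential") else int(rng.binomial(n, p))
        rows.append({"gene": t["gene"], "line_genotype": "tm1a/+",
                     "colonies_screened": n, "colonies_positive": het_pos})
    return pd.DataFrame(rows), truth
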