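"""pI_hygGFP insertion-vector construction pipeline.

From an IKMC-style Intermediate Vector (homology arms G5..U3 / D5..G3 with a
loxP-flanked critical-exon region carrying an rpsL counter-selection marker,
Gateway attR1..attR4 sites) the pipeline runs a three-way Gateway exchange
with the PmeI/loxP adaptor module and one of three reading-frame variants of
the hygromycin-GFP trap cassette, then a bacterial Cre step that deletes the
floxed critical exon + rpsL (creating the genomic gap that the ex5 PCR
screen depends on), verifies the product can be opened at a unique PmeI
site, and linearizes it for electroporation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import parts
from .alleles import GeneModel, end_phase
from .errors import (
    AssemblyLogicError,
    CoordinateError,
    NoFrameError,
    UnsuitableVectorError,
)
from .recombine import gateway_three_way, linearize, ssr_excise
from .seqmodel import AnnotatedSequence, Interval, scan_motif

logger = logging.getLogger(__name__)

PMEI = parts.PMEI_SITE

#: expected assembled Intermediate Vector size (QC digest expectation only)
IV_EXPECTED_SIZE = 15_000
IV_SIZE_TOLERANCE = 0.30


@dataclass
class IntermediateVectorSpec:
    """Geometry of one Intermediate Vector against its genomic locus.

    ``arm5`` spans G5..U3, ``critical_region`` U3..D5 (holds the critical
    exon and the ex5 site), ``arm3`` D5..G3, all on the coding strand of
    the genome record.
    """

    gene_id: str
    arm5: Interval
    critical_region: Interval
    arm3: Interval
    plasmid: AnnotatedSequence | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.arm5.start < self.arm5.end == self.critical_region.start
                < self.critical_region.end == self.arm3.start < self.arm3.end):
            raise CoordinateError(
                f"{self.gene_id}: G5 < U3 < D5 < G3 ordering violated")

    def homology_interval(self) -> Interval:
        return Interval(self.arm5.start, self.arm3.end)

    def qc_size(self) -> None:
        if self.plasmid is None:
            return
        lo = IV_EXPECTED_SIZE * (1 - IV_SIZE_TOLERANCE)
        hi = IV_EXPECTED_SIZE * (1 + IV_SIZE_TOLERANCE)
        if not lo <= len(self.plasmid) <= hi:
            logger.warning("%s: assembled Intermediate Vector is %d nt, outside "
                           "the ~%d nt QC window", self.gene_id,
                           len(self.plasmid), IV_EXPECTED_SIZE)


def check_pmei_suitability(spec: IntermediateVectorSpec,
                           genome: AnnotatedSequence,
                           motif: str = PMEI) -> dict:
    """A design is suitable iff its homology region (both arms plus the
    critical-exon region) is free of the linearization motif — the adaptor
    supplies the single intended site, and any extra one means the final
    vector cannot be linearized intact."""
    hom = spec.homology_interval()
    if not (0 <= hom.start < hom.end <= len(genome)):
        raise CoordinateError(
            f"{spec.gene_id}: homology region outside genome bounds")
    region = genome.slice(hom.start, hom.end)
    extra = [iv.shift(hom.start) for iv in scan_motif(region, motif, both_strands=True)]
    return {"suitable": not extra, "extra_sites": extra}


def select_frame_cassette(gene: GeneModel, homology: Interval,
                          library: dict[int, AnnotatedSequence]) -> AnnotatedSequence:
    """Pick the trap-cassette variant whose reading frame matches the end
    phase of the most 3' exon within the genomic homology region."""
    phase = end_phase(gene, homology)
    try:
        return library[phase]
    except KeyError:
        raise NoFrameError(f"cassette library lacks frame {phase}") from None


def build_pI_hygGFP(spec: IntermediateVectorSpec,
                    adaptor: AnnotatedSequence,
                    cassette_library: dict[int, AnnotatedSequence],
                    gene: GeneModel,
                    genome: AnnotatedSequence,
                    trap_donor_builder=None) -> dict:
    """Full construction pipeline; returns ``{"vector", "report"}``.

    Stages: suitability gate -> frame selection -> three-way Gateway ->
    bacterial Cre (deletes critical exon + rpsL, leaving one loxP and the
    genomic gap) -> single-PmeI verification -> linearization.
    """
    from .fixtures import make_trap_donor  # circular-import shim

    suit = check_pmei_suitability(spec, genome)
    if not suit["suitable"]:
        raise UnsuitableVectorError(
            f"{spec.gene_id}: {len(suit['extra_sites'])} extra PmeI site(s) in the "
            "homology region; vector cannot be linearized intact")
    cassette = select_frame_cassette(gene, spec.homology_interval(), cassette_library)
    phase = cassette.find(kind="cassette")[0].qualifiers["frame_phase"]
    builder = trap_donor_builder or make_trap_donor
    trap_donor = builder(cassette)
    gw = gateway_three_way(spec.plasmid, adaptor, trap_donor)
    cre = ssr_excise(gw["product"], "loxP")
    vector_circ = cre["main"]
    if vector_circ.find(kind="marker", marker="rpsL"):
        raise AssemblyLogicError(
            f"{spec.gene_id}: rpsL still present after the bacterial Cre step")
    vector = linearize(vector_circ, PMEI)
    vector.id = f"pI_hygGFP_{spec.gene_id}"
    gap = spec.critical_region
    report = {
        "gene": spec.gene_id,
        "frame_phase": phase,
        "gap_interval": (gap.start, gap.end),
        "final_length": len(vector),
        "n_loxP": len(vector.find(kind="recomb_site", subtype="loxP")),
        "byproduct_lengths": [len(b) for b in gw["byproducts"]],
    }
    return {"vector": vector, "report": report}


# -- bacterial selection ---------------------------------------------------

_DRUG_MARKER = {"kan": "kan", "chloramphenicol": "cat", "amp": "amp",
                "zeo": "zeo", "nat": "nat", "G418": "neo", "hygromycin": "hygro"}


def simulate_bacterial_selection(construct: AnnotatedSequence,
                                 media: set[str]) -> bool:
    """Colony growth of a DH10B-style rpsL+ host carrying ``construct``.

    Growth requires a replication origin, a resistance marker for every
    antibiotic in the media, and — because plasmid-borne rpsL dominantly
    restores streptomycin sensitivity — the absence of rpsL whenever
    streptomycin is present.
    """
    if not construct.find(kind="origin"):
        return False
    markers = {f.qualifiers["marker_name"] for f in construct.find(kind="marker")}
    for drug in media:
        if drug == "strep":
            if "rpsL" in markers:
                return False
        else:
            need = _DRUG_MARKER.get(drug)
            if need is None:
                raise KeyError(f"unknown antibiotic {drug!r}")
            if need not in markers:
                return False
    return True


def screen_vector_panel(specs: list[IntermediateVectorSpec],
                        genomes: dict[str, AnnotatedSequence] | AnnotatedSequence,
                        motif: str = PMEI) -> dict:
    """Per-design PmeI suitability plus the aggregate unsuitable fraction.

    ``genomes`` may be a single record or a mapping gene_id -> record.
    """
    rows = []
    for spec in specs:
        genome = genomes[spec.gene_id] if isinstance(genomes, dict) else genomes
        res = check_pmei_suitability(spec, genome, motif)
        rows.append({"gene": spec.gene_id,
                     "design": spec.meta.get("design", "promoterless"),
                     "suitable": res["suitable"],
                     "extra_site_count": len(res["extra_sites"])})
    table = pd.DataFrame(rows, columns=["gene", "design", "suitable",
                                        "extra_site_count"])
    if len(table):
        frac = float((~table["suitable"]).mean())
        summary = {"n_designs": len(table),
                   "n_unsuitable": int((~table["suitable"]).sum()),
                   "unsuitable_fraction": frac,
                   "unsuitable_pct": round(100 * frac, 1)}
    else:
        summary = {"n_designs": 0, "n_unsuitable": 0,
                   "unsuitable_fraction": float("nan"),
                   "unsuitable_pct": float("nan"), "empty": True}
        logger.warning("empty vector panel; unsuitable fraction undefined")
    return {"table": table, "summary": summary}
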