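"""Allele construction, the tm-state machine, and selection/expression logic.

Allele states follow the conditional knockout nomenclature:

* ``wt``   — unmodified locus.
* ``tm1a`` — knockout-first: FRT-flanked promoterless beta-geo splice trap in
  the intron upstream of a loxP-flanked critical exon.  Null by trapping.
* ``tm1b`` — Cre product of tm1a: critical exon deleted, trap retained.
* ``tm1c`` — Flp product of tm1a: trap removed (one FRT scar), conditional.
* ``tm1d`` — Cre product of tm1c: critical exon deleted, frameshift null.
* ``tm2``  — second-allele insertion-trap null made with the pI_hygGFP
  vector: duplicated homology flanking a hygromycin-GFP splice trap, the
  gap-repaired region carrying the ex5 screening site.

A :class:`CellLine` is an ordered pair of alleles plus unlinked transgenes
(CreERT2) and the two stochastic parameters of the inducible system:
``leak_rate`` (recombination without induction) and ``escaper_rate``
(failure to recombine on induction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from . import parts
from .errors import ConfigError, ConstructionError, NoFrameError, ProtocolError
from .recombine import integrate_insertion_vector, random_integrate, ssr_excise
from .seqmodel import AnnotatedSequence, Feature, Interval, concat

logger = logging.getLogger(__name__)

ALLELE_STATES = ("wt", "tm1a", "tm1b", "tm1c", "tm1d", "tm2")

#: minimum ES-cell expression (% of the transferrin-receptor reference)
#: for a promoterless splice trap to confer drug resistance
DEFAULT_EXPRESSION_THRESHOLD = 1.0

DRUG_MARKERS = {"hygromycin": "hygro", "G418": "neo", "puromycin": "puro"}


@dataclass
class GeneModel:
    """Exon/CDS structure plus the ES-cell context the method depends on."""

    gene_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    expression_pct_trfr: float = 100.0
    essential_in_es: bool = False
    critical_exon_index: int = 2        # 0-based index into ``exons``
    landmarks: dict = field(default_factory=dict)   # g5, u3, d5, g3, ...

    @property
    def critical_exon(self) -> Interval:
        return self.exons[self.critical_exon_index]

    @property
    def expressed(self) -> bool:
        return self.expression_pct_trfr >= DEFAULT_EXPRESSION_THRESHOLD


@dataclass
class AlleleMap:
    """One chromosomal allele: annotated locus sequence + symbolic state."""

    seq: AnnotatedSequence
    state: str
    provenance: list = field(default_factory=list)

    def genotype_symbol(self) -> str:
        return "+" if self.state == "wt" else self.state


@dataclass
class CellLine:
    allele_a: AlleleMap
    allele_b: AlleleMap
    gene: GeneModel
    transgenes: set = field(default_factory=set)
    leak_rate: float = 0.0
    escaper_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.leak_rate, self.escaper_rate):
            if not 0.0 <= r <= 1.0:
                raise ConstructionError(f"rate {r} outside [0, 1]")

    @property
    def genotype(self) -> str:
        """Community shorthand, mutant allele written first (e.g. tm1a/+)."""
        a, b = self.allele_a.genotype_symbol(), self.allele_b.genotype_symbol()
        if a == "+" and b != "+":
            a, b = b, a
        return f"{a}/{b}"

    def alleles(self) -> tuple[AlleleMap, AlleleMap]:
        return (self.allele_a, self.allele_b)


# -- reading frame ---------------------------------------------------------

def end_phase(gene: GeneModel, homology: Interval) -> int:
    """Cumulative coding length (nt) from the CDS start through the end of
    the most 3' exon wholly inside ``homology``, modulo 3."""
    inside = [e for e in gene.exons
              if e.start >= homology.start and e.end <= homology.end]
    coding = [e for e in inside
              if any(c.start < e.end and c.end > e.start for c in gene.cds)]
    if not coding:
        raise NoFrameError(
            f"no coding exon of {gene.gene_id} inside ({homology.start},{homology.end})")
    last = max(coding, key=lambda e: e.end)
    cum = sum(c.length() for c in gene.cds if c.end <= last.end)
    return cum % 3


# -- allele construction ---------------------------------------------------

def _lr_tag() -> AnnotatedSequence:
    """Vector-derived tag 3' of the distal loxP; the LR reverse primer
    binds here on tm1a/tm1c/tm1d templates (absent from tm2)."""
    tag = parts.random_dna(np.random.default_rng(171717), 40, parts._FORBIDDEN)
    s = AnnotatedSequence(tag, id="lr_tag")
    s.add_feature(Feature("LR", "primer_site", Interval(10, 30, "-")))
    return s


def _r1_site() -> AnnotatedSequence:
    """Forward vector-derived site between the FRT scar and the 5' loxP;
    template of the cis/trans junction assay (R1_amp_F2)."""
    tag = parts.random_dna(np.random.default_rng(515151), 20, parts._FORBIDDEN)
    s = AnnotatedSequence(tag, id="r1_site")
    s.add_feature(Feature("R1_amp_F2", "primer_site", Interval(0, 20, "+")))
    return s


def _site_seq(subtype: str) -> AnnotatedSequence:
    core = {"loxP": parts.LOXP, "FRT": parts.FRT}[subtype]
    s = AnnotatedSequence(core, id=subtype)
    s.add_feature(parts.site_feature(subtype, 0))
    return s


def build_tm1a(gene: GeneModel, genome: AnnotatedSequence,
               beta_geo: AnnotatedSequence | None = None) -> AlleleMap:
    """Assemble the knockout-first allele on a wild-type locus.

    Inserts ``FRT | beta-geo trap | FRT | R1 site | loxP`` at the 5'
    boundary of the critical-exon region (u3) and ``loxP | LR tag`` at its
    3' boundary (d5).
    """
    lm = gene.landmarks
    if "u3" not in lm or "d5" not in lm:
        raise ConstructionError(
            f"{gene.gene_id} has no u3/d5 landmarks; no qualifying intron")
    u3, d5 = lm["u3"], lm["d5"]
    cas = beta_geo if beta_geo is not None else parts.beta_geo_cassette()
    insert5 = concat([_site_seq("FRT"), cas, _site_seq("FRT"),
                      _r1_site(), _site_seq("loxP")], id="tm1a_insert5")
    insert3 = concat([_site_seq("loxP"), _lr_tag()], id="tm1a_insert3")
    seq = concat([genome.slice(0, u3), insert5, genome.slice(u3, d5),
                  insert3, genome.slice(d5, len(genome))],
                 id=f"{gene.gene_id}_tm1a")
    allele = AlleleMap(seq, "tm1a", provenance=["build_tm1a"])
    validate_allele(allele, gene)
    return allele


def wild_type_allele(gene: GeneModel, genome: AnnotatedSequence) -> AlleleMap:
    return AlleleMap(genome.copy(id=f"{gene.gene_id}_wt"), "wt")


_TRANSITIONS = {
    ("tm1a", "Flp"): "tm1c",
    ("tm1a", "Cre"): "tm1b",
    ("tm1b", "Flp"): "tm1d",
    ("tm1c", "Cre"): "tm1d",
}


def apply_recombinase(allele: AlleleMap, enzyme: str) -> AlleleMap:
    """Cre or Flp on one allele; delegates to the excision engine and
    advances the tm state per the transition table.  States without two
    cognate sites are returned unchanged with a warning."""
    if enzyme not in {"Cre", "Flp"}:
        raise ConfigError(f"unknown recombinase {enzyme!r}")
    subtype = "loxP" if enzyme == "Cre" else "FRT"
    res = ssr_excise(allele.seq, subtype)
    if res["excised_circle"] is None:
        return allele
    new_state = _TRANSITIONS.get((allele.state, enzyme), allele.state)
    out = AlleleMap(res["main"], new_state,
                    provenance=allele.provenance + [f"{enzyme}"])
    out.seq.id = f"{allele.seq.id.split('_tm')[0]}_{new_state}"
    return out


# -- census validation -----------------------------------------------------

def _counts(allele: AlleleMap, gene: GeneModel) -> dict:
    seq = allele.seq
    ce_label = f"exon{gene.critical_exon_index + 1}"
    return {
        "FRT": len(seq.find(kind="recomb_site", subtype="FRT")),
        "loxP": len(seq.find(kind="recomb_site", subtype="loxP")),
        "beta_geo": len(seq.find(kind="cassette", marker="beta-geo")),
        "hyg_gfp": len(seq.find(kind="cassette", marker="hygro-GFP")),
        "critical_exon": len(seq.find(kind="exon", label=ce_label)),
        "ex5": len(seq.find(kind="primer_site", label="ex5")),
    }


_CENSUS = {
    "wt":   dict(FRT=0, loxP=0, beta_geo=0, hyg_gfp=0, critical_exon=1),
    "tm1a": dict(FRT=2, loxP=2, beta_geo=1, hyg_gfp=0, critical_exon=1),
    "tm1b": dict(FRT=2, loxP=1, beta_geo=1, hyg_gfp=0, critical_exon=0),
    "tm1c": dict(FRT=1, loxP=2, beta_geo=0, hyg_gfp=0, critical_exon=1),
    "tm1d": dict(FRT=1, loxP=1, beta_geo=0, hyg_gfp=0, critical_exon=0),
    "tm2":  dict(FRT=0, loxP=1, beta_geo=0, hyg_gfp=1, critical_exon=2, ex5=2),
}


def validate_allele(allele: AlleleMap, gene: GeneModel) -> None:
    """State-specific feature census; raises on any mismatch."""
    if allele.state not in _CENSUS:
        raise ConstructionError(f"unknown allele state {allele.state!r}")
    have = _counts(allele, gene)
    for key, want in _CENSUS[allele.state].items():
        if have[key] != want:
            raise ConstructionError(
                f"{allele.seq.id}: state {allele.state} census failed on "
                f"{key} (have {have[key]}, want {want})")


# -- expression / selection ------------------------------------------------

def _first_trap(seq: AnnotatedSequence):
    """First splice-trap (acceptor + cassette + polyA) downstream of an exon
    but upstream of the next retained exon; returns (cassette_feature,
    junction_exon_end) or None."""
    exons = seq.find(kind="exon")
    acceptors = seq.find(kind="splice_acceptor")
    polyas = seq.find(kind="polyA")
    cassettes = seq.find(kind="cassette")
    L = len(seq)
    for i, ex in enumerate(exons):
        nxt = exons[i + 1].start if i + 1 < len(exons) else L
        for sa in acceptors:
            if ex.end <= sa.start < nxt:
                for pa in polyas:
                    if sa.end <= pa.start and pa.end <= nxt:
                        for cas in cassettes:
                            if cas.start <= sa.start and cas.end >= pa.start:
                                return cas, ex.end
    return None


def _coding_nt_upstream(seq: AnnotatedSequence, pos: int) -> int:
    return sum(f.interval.length() for f in seq.find(kind="cds_segment")
               if f.end <= pos)


def expression_outcome(allele: AlleleMap, gene: GeneModel,
                       threshold: float = DEFAULT_EXPRESSION_THRESHOLD) -> dict:
    """What this allele expresses in ES cells.

    The transcript is walked from the promoter; the first splice-acceptor
    cassette with a polyA terminates the message.  beta-geo markers need
    only locus expression above ``threshold`` (internal translation entry);
    the hygromycin-GFP trap additionally requires its reading-frame variant
    to match the end phase of the last spliced endogenous exon.
    """
    expressed = gene.expression_pct_trfr >= threshold
    trap = _first_trap(allele.seq)
    markers: set[str] = set()
    full = False
    truncated = None
    n_exons = len(allele.seq.find(kind="exon"))
    if trap is None:
        full = n_exons >= len(gene.exons)
        if not full:
            truncated = "frameshift"
    else:
        cas, junction = trap
        name = cas.qualifiers.get("marker_name")
        truncated = "trap"
        if name == "beta-geo" and expressed:
            markers |= {"lacZ", "neo"}
        elif name == "hygro-GFP" and expressed:
            phase = _coding_nt_upstream(allele.seq, junction) % 3
            if phase == cas.qualifiers.get("frame_phase"):
                markers |= {"hygro", "GFP"}
    return {"full_protein": full, "truncation": truncated,
            "markers_expressed": markers}


def predict_truncation(allele: AlleleMap, gene: GeneModel) -> dict:
    """Length and approximate mass of the truncated product of a disrupted
    allele.

    Trapped alleles: the endogenous residues upstream of the trap junction,
    ``floor(coding nt / 3)``.  Critical-exon deletions: translation of the
    frameshifted message through to the first stop.  Mass uses the 110.5 Da
    average residue mass.
    """
    trap = _first_trap(allele.seq)
    if trap is not None:
        aa = _coding_nt_upstream(allele.seq, trap[1]) // 3
        return {"aa_length": aa, "approx_mass_kda": mass_kda(aa)}
    from .seqmodel import splice_transcript
    mrna = splice_transcript(allele.seq)
    cds = mrna.find(kind="cds_segment")
    if not cds:
        return {"aa_length": 0, "approx_mass_kda": 0}
    start = cds[0].start
    coding = mrna.residues[start:]
    coding = coding[: len(coding) // 3 * 3]
    prot = Seq(coding).translate(to_stop=True)
    return {"aa_length": len(prot), "approx_mass_kda": mass_kda(len(prot))}


def mass_kda(aa_length: int) -> int:
    """Nearest-integer kDa from a residue count (110.5 Da average mass)."""
    return round(aa_length * 110.5 / 1000)


# -- targeting-step enumeration --------------------------------------------

def _integrated_allele(target: AlleleMap, vector: AnnotatedSequence) -> AlleleMap:
    product = integrate_insertion_vector(target.seq, vector)
    state = "tm2" if target.state == "wt" else f"{target.state}::tm2cis"
    return AlleleMap(product, state, provenance=target.provenance + ["pI_hygGFP"])


def _viable(line: CellLine) -> bool:
    if not line.gene.essential_in_es:
        return True
    return any(expression_outcome(a, line.gene)["full_protein"]
               for a in line.alleles())


def simulate_targeting_step(cells: CellLine, vector: AnnotatedSequence,
                            selection: str = "hygromycin") -> dict:
    """Enumerate integration targets x outcomes for one electroporation.

    A genotype is recoverable iff the selection marker is expressed from
    some allele (expression_outcome) AND the line is viable (an essential
    gene needs one functional allele).  Random integrations never express
    the promoterless trap and are never recoverable.
    """
    if selection not in DRUG_MARKERS:
        raise ConfigError(f"unknown selection drug {selection!r}")
    marker = DRUG_MARKERS[selection]
    outcomes = []
    for which in ("allele_a", "allele_b"):
        target = getattr(cells, which)
        new = _integrated_allele(target, vector)
        line = CellLine(
            allele_a=new if which == "allele_a" else cells.allele_a,
            allele_b=new if which == "allele_b" else cells.allele_b,
            gene=cells.gene, transgenes=set(cells.transgenes),
            leak_rate=cells.leak_rate, escaper_rate=cells.escaper_rate,
            seed=cells.seed)
        expressed = any(marker in expression_outcome(a, cells.gene)["markers_expressed"]
                        for a in line.alleles())
        recoverable = expressed and _viable(line)
        outcomes.append({"target": which, "line": line, "class": "targeted",
                         "marker_expressed": expressed, "viable": _viable(line),
                         "recoverable": recoverable})
    outcomes.append({"target": "random", "line": None, "class": "random",
                     "marker_expressed": False, "viable": True,
                     "recoverable": False})
    recoverable = [o for o in outcomes if o["recoverable"]]
    return {"outcomes": outcomes,
            "recoverable_genotypes": sorted({o["line"].genotype for o in recoverable})}


# -- multi-step protocol simulation ----------------------------------------

def _convert_line(line: CellLine) -> CellLine | None:
    """tm1c -> tm1d on whichever allele is convertible; None if none is."""
    for which in ("allele_a", "allele_b"):
        a = getattr(line, which)
        if a.state == "tm1c":
            new = apply_recombinase(a, "Cre")
            return CellLine(
                allele_a=new if which == "allele_a" else line.allele_a,
                allele_b=new if which == "allele_b" else line.allele_b,
                gene=line.gene, transgenes=set(line.transgenes),
                leak_rate=line.leak_rate, escaper_rate=line.escaper_rate,
                seed=line.seed)
    return None


def simulate_protocol(steps: list, start: CellLine,
                      n_cells: int = 100_000) -> dict:
    """Run an ordered workflow on a cell population.

    Steps (dicts or (name, arg) tuples): ``flp``, ``electroporate`` (vector)
    followed by ``select`` (drug), ``knockin_creert2``, ``induce_4oht``
    (hours), ``subclone``.  Deterministic transitions plus binomial
    leak/escaper fractions drawn from the line's seed.  The trajectory
    records per-step population fractions by genotype; the report includes
    the residual non-recombined escaper fraction.
    """
    rng = np.random.default_rng(start.seed)
    population: dict[str, tuple[CellLine, float]] = {start.genotype: (start, 1.0)}
    pending_vector: AnnotatedSequence | None = None
    post_induction_escapers: float | None = None
    trajectory = [{"step": "start",
                   "population": {g: f for g, (_, f) in population.items()}}]

    def apply_leak():
        if start.leak_rate <= 0:
            return
        updates = {}
        for g, (line, frac) in list(population.items()):
            if "CreERT2" not in line.transgenes:
                continue
            conv = _convert_line(line)
            if conv is None:
                continue
            leaked = rng.binomial(n_cells, start.leak_rate) / n_cells
            if leaked > 0:
                population[g] = (line, frac * (1 - leaked))
                updates[conv.genotype] = (conv, frac * leaked)
        for g, (line, frac) in updates.items():
            old = population.get(g, (line, 0.0))[1]
            population[g] = (line, old + frac)

    for step in steps:
        if isinstance(step, str):
            name, arg = step, None
        elif isinstance(step, dict):
            (name, arg), = step.items()
        else:
            name, arg = step
        if name == "flp":
            population = {
                line2.genotype: (line2, frac)
                for line2, frac in (
                    (CellLine(apply_recombinase(line.allele_a, "Flp"),
                              apply_recombinase(line.allele_b, "Flp"),
                              line.gene, set(line.transgenes),
                              line.leak_rate, line.escaper_rate, line.seed), frac)
                    for line, frac in population.values())}
        elif name == "electroporate":
            pending_vector = arg
        elif name == "select":
            if pending_vector is None:
                raise ProtocolError("select without a preceding electroporation")
            new_pop = {}
            for line, frac in population.values():
                res = simulate_targeting_step(line, pending_vector, arg)
                for o in res["outcomes"]:
                    if o["recoverable"]:
                        # trans targeting of the remaining wild-type allele is
                        # the designed outcome; cis events are carried too
                        g = o["line"].genotype
                        new_pop.setdefault(g, (o["line"], 0.0))
                        new_pop[g] = (o["line"], new_pop[g][1] + frac)
            total = sum(f for _, f in new_pop.values()) or 1.0
            population = {g: (l, f / total) for g, (l, f) in new_pop.items()}
            pending_vector = None
        elif name == "knockin_creert2":
            population = {
                g: (CellLine(line.allele_a, line.allele_b, line.gene,
                             set(line.transgenes) | {"CreERT2"},
                             line.leak_rate, line.escaper_rate, line.seed), f)
                for g, (line, f) in population.items()}
        elif name == "induce_4oht":
            if not any("CreERT2" in line.transgenes
                       for line, _ in population.values()):
                raise ProtocolError("4'OHT induction without a CreERT2 transgene")
            updates: dict[str, tuple[CellLine, float]] = {}
            for g, (line, frac) in list(population.items()):
                conv = _convert_line(line)
                if conv is None:
                    continue
                escaped = (rng.binomial(n_cells, start.escaper_rate) / n_cells
                           if start.escaper_rate > 0 else 0.0)
                population[g] = (line, frac * escaped)
                old = updates.get(conv.genotype, (conv, 0.0))[1]
                updates[conv.genotype] = (conv, old + frac * (1 - escaped))
            population.update(updates)
            population = {g: (l, f) for g, (l, f) in population.items() if f > 0}
            post_induction_escapers = sum(
                f for line, f in population.values()
                if any(a.state == "tm1c" for a in line.alleles()))
        elif name == "screen_trans":
            # cis/trans junction screen: discard clones where one allele
            # carries both the knockout-first remnant and the hygro trap
            population = {
                g: (line, f) for g, (line, f) in population.items()
                if not any(
                    a.seq.find(kind="primer_site", label="R1_amp_F2")
                    and a.seq.find(kind="cassette", marker="hygro-GFP")
                    for a in line.alleles())}
            total = sum(f for _, f in population.values()) or 1.0
            population = {g: (l, f / total) for g, (l, f) in population.items()}
        elif name == "subclone":
            g, (line, _) = max(population.items(), key=lambda kv: kv[1][1])
            population = {g: (line, 1.0)}
        else:
            raise ProtocolError(f"unknown protocol step {name!r}")
        if name != "induce_4oht":
            apply_leak()
        trajectory.append({"step": name,
                           "population": {g: round(f, 6)
                                          for g, (_, f) in population.items()}})

    escaper_fraction = post_induction_escapers if post_induction_escapers is not None \
        else sum(f for line, f in population.values()
                 if any(a.state == "tm1c" for a in line.alleles()))
    final = {g: f for g, (_, f) in population.items()}
    return {"trajectory": trajectory, "final_population": final,
            "escaper_fraction": escaper_fraction,
            "final_lines": {g: line for g, (line, _) in population.items()}}
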