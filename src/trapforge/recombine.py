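"""Site-specific and homologous recombination engine.

Gateway exchange is modelled as typed-feature matching on att sites (the
community placeholder-core realization carries the residues), Cre/Flp as
excision between directly repeated loxP/FRT sites, insertion targeting as a
single crossover with double-strand gap repair, and random integration as
blunt end-joining.  Every operation conserves residues up to the
bookkeeping stated in its docstring and emits a JSON-serializable event
record via :data:`EVENT_LOG`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .errors import (
    AmbiguousSiteError,
    MissingSiteError,
    MultipleSiteError,
    MustLinearizeError,
    NoIntegrationError,
    NoSiteError,
    OrientationError,
)
from .parts import PMEI_CUT_OFFSET
from .seqmodel import AnnotatedSequence, Feature, Interval, concat, scan_motif

logger = logging.getLogger(__name__)

#: In-memory recombination event log (list of dicts, JSON-lines friendly).
EVENT_LOG: list[dict] = []


def _log_event(operation: str, **info) -> None:
    EVENT_LOG.append({"operation": operation, **info})
    logger.info("recombination event: %s %s", operation, info)


def _single_site(seq: AnnotatedSequence, subtype: str) -> Feature:
    feats = seq.find(kind="recomb_site", subtype=subtype)
    if not feats:
        raise MissingSiteError(f"{seq.id} lacks {subtype}")
    if len(feats) > 1:
        raise AmbiguousSiteError(f"{seq.id} carries {len(feats)} {subtype} sites")
    return feats[0]


def _relabel_att(seq: AnnotatedSequence, to_class: str) -> None:
    """Rewrite attL*/attR* subtypes in place to attB*/attP* of same index."""
    new = []
    for f in seq.features:
        st = f.qualifiers.get("site_subtype", "")
        if st.startswith(("attL", "attR", "attB", "attP")):
            idx = st[-1]
            quals = dict(f.qualifiers)
            quals["site_subtype"] = f"{to_class}{idx}"
            f = replace(f, label=f"{to_class}{idx}", qualifiers=quals)
        new.append(f)
    seq.features = new


def _payload(donor: AnnotatedSequence, left: str, right: str,
             id: str) -> tuple[AnnotatedSequence, AnnotatedSequence]:
    """Split a circular donor into (payload, backbone) between two att sites.

    Payload runs from the 3' end of ``left`` to the 5' start of ``right``
    going forward around the circle; the sites themselves stay with neither
    half (the acceptor keeps its own site copies, relabelled)."""
    lf = _single_site(donor, left)
    rf = _single_site(donor, right)
    if lf.strand != rf.strand:
        raise OrientationError(f"{left}/{right} not co-oriented on {donor.id}")
    rot = donor.rotate(lf.end)
    L = len(donor)
    span = (rf.start - lf.end) % L
    payload = rot.slice(0, span, id=f"{id}_payload") if span else \
        AnnotatedSequence("", id=f"{id}_payload")
    backbone = rot.slice(span, L, id=f"{id}_backbone")  # incl. both donor sites
    return payload, backbone


def gateway_three_way(intermediate: AnnotatedSequence,
                      adaptor: AnnotatedSequence,
                      trap: AnnotatedSequence) -> dict:
    """Three-part Gateway exchange.

    The acceptor (Intermediate Vector) carries attR1..attR4.  The segment
    between attR1 and attR2 is replaced by the adaptor's attL1/attL2
    payload; the segment between attR3 and attR4 (the plasmid backbone) is
    replaced by the trap donor's attL3/attL4 payload.  All att sites in the
    product are relabelled attB1..attB4; displaced segments are returned as
    circular byproducts carrying attP sites.

    Returns ``{"product": ..., "byproducts": [...]}``.
    """
    for st in ("attR1", "attR2", "attR3", "attR4"):
        _single_site(intermediate, st)
    r1, r2 = (_single_site(intermediate, s) for s in ("attR1", "attR2"))
    r3, r4 = (_single_site(intermediate, s) for s in ("attR3", "attR4"))
    if len({r1.strand, r2.strand, r3.strand, r4.strand}) != 1:
        raise OrientationError("attR sites on the acceptor are not co-oriented")
    if not intermediate.is_circular:
        raise MustLinearizeError("Gateway acceptor must be circular")

    pay12, back12 = _payload(adaptor, "attL1", "attL2", adaptor.id)
    pay34, back34 = _payload(trap, "attL3", "attL4", trap.id)

    # rotate the acceptor so attR1 starts at 0; order around the circle is
    # then R1 .. R2 .. (kept arc) .. R3 .. R4 .. (kept arc) .. back to R1
    rot = intermediate.rotate(r1.start)
    r1, r2 = (_single_site(rot, s) for s in ("attR1", "attR2"))
    r3, r4 = (_single_site(rot, s) for s in ("attR3", "attR4"))
    if not (r1.start < r2.start < r3.start < r4.start):
        raise OrientationError("attR1..attR4 are not in circular order on the acceptor")

    site1 = rot.slice(r1.start, r1.end)
    site2 = rot.slice(r2.start, r2.end)
    site3 = rot.slice(r3.start, r3.end)
    site4 = rot.slice(r4.start, r4.end)
    displaced12 = rot.slice(r1.end, r2.start, id="displaced_R1R2") \
        if r2.start > r1.end else AnnotatedSequence("", id="displaced_R1R2")
    kept_a = rot.slice(r2.end, r3.start, id="kept_a")
    displaced34 = rot.slice(r3.end, r4.start, id="displaced_R3R4")
    kept_b = rot.slice(r4.end, len(rot), id="kept_b") if r4.end < len(rot) else None

    parts = [site1, pay12, site2, kept_a, site3, pay34, site4]
    if kept_b is not None:
        parts.append(kept_b)
    product = concat(parts, id=f"{intermediate.id}_xchg", topology="circular")
    _relabel_att(product, "attB")

    by1 = concat([site1.copy(), displaced12, site2.copy(), back12],
                 id="byproduct_R1R2", topology="circular")
    by2 = concat([site3.copy(), displaced34, site4.copy(), back34],
                 id="byproduct_R3R4", topology="circular")
    for by in (by1, by2):
        _relabel_att(by, "attP")
    _log_event("gateway_three_way", inputs=[intermediate.id, adaptor.id, trap.id],
               product=product.id, product_len=len(product))
    return {"product": product, "byproducts": [by1, by2]}


def ssr_excise(seq: AnnotatedSequence, site_subtype: str) -> dict:
    """Cre/Flp excision between two directly repeated sites.

    The segment between the sites is removed; the first site copy is
    retained in the main product and the excised segment is returned as a
    circle carrying the second copy.  Zero or one site: identity with a
    warning.  More than two: ambiguity error.  Inverted repeats: error.

    Returns ``{"main": ..., "excised_circle": ... or None}``.
    """
    if site_subtype not in {"loxP", "FRT"}:
        raise ValueError(f"unsupported site subtype {site_subtype!r}")
    sites = seq.find(kind="recomb_site", subtype=site_subtype)
    if len(sites) < 2:
        logger.warning("%s: %d %s site(s); excision is a no-op",
                       seq.id, len(sites), site_subtype)
        return {"main": seq.copy(), "excised_circle": None}
    if len(sites) > 2:
        raise AmbiguousSiteError(
            f"{seq.id} carries {len(sites)} {site_subtype} sites; excision ambiguous")
    s1, s2 = sites
    if s1.strand != s2.strand:
        raise OrientationError(
            f"{site_subtype} sites on {seq.id} are inverted repeats; unsupported")
    if seq.is_circular:
        rot = seq.rotate(s1.start)
        s1, s2 = rot.find(kind="recomb_site", subtype=site_subtype)
        main = concat([rot.slice(s1.start, s1.end), rot.slice(s2.end, len(rot))],
                      id=f"{seq.id}_{site_subtype}x", topology="circular") \
            if s2.end < len(rot) else \
            rot.slice(s1.start, s1.end, id=f"{seq.id}_{site_subtype}x")
        excised = rot.slice(s1.end, s2.end, id=f"{seq.id}_circle")
        excised.topology = "circular"
    else:
        main = concat([seq.slice(0, s1.end),
                       seq.slice(s2.end, len(seq))] if s2.end < len(seq)
                      else [seq.slice(0, s1.end)],
                      id=f"{seq.id}_{site_subtype}x")
        excised = seq.slice(s1.end, s2.end, id=f"{seq.id}_circle")
        excised.topology = "circular"
    _log_event("ssr_excise", input=seq.id, site=site_subtype,
               removed=len(excised), product=main.id)
    return {"main": main, "excised_circle": excised}


def linearize(seq: AnnotatedSequence, motif: str = "GTTTAAAC") -> AnnotatedSequence:
    """Open a circular plasmid at its unique blunt-cutter site.

    Exactly one occurrence is required: none raises :class:`NoSiteError`,
    two or more raise :class:`MultipleSiteError` — a vector with extra
    sites inside its homology arms cannot be linearized intact.
    """
    if not seq.is_circular:
        raise MustLinearizeError(f"{seq.id} is already linear")
    hits = scan_motif(seq, motif, both_strands=True)
    if not hits:
        raise NoSiteError(f"no {motif} site on {seq.id}")
    if len(hits) > 1:
        raise MultipleSiteError(
            f"{len(hits)} {motif} sites on {seq.id}; cannot be linearized intact")
    cut = (hits[0].start + PMEI_CUT_OFFSET) % len(seq)
    out = seq.linearized_at(cut, id=f"{seq.id}_lin")
    _log_event("linearize", input=seq.id, cut=cut, product=out.id)
    return out


def _find_subseq(hay: str, needle: str) -> int:
    return hay.find(needle)


def integrate_insertion_vector(allele_seq: AnnotatedSequence,
                               vector: AnnotatedSequence) -> AnnotatedSequence:
    """Single-crossover integration of a gapped insertion vector.

    The vector must be linear (opened at the PmeI site inside its homology
    region) and carry ``homology_arm`` features ``arm5`` and ``arm3`` whose
    residues match the allele exactly.  Integration duplicates the homology:
    the product is

        5' flank | copy 1 (vector-derived, gap repaired from the
        chromosomal template, adaptor loxP at the repair junction) |
        trap cassette | copy 2 (chromosomal) | 3' flank

    Repair synthesis copies whatever the template holds between the two
    arms — the wild-type critical-exon region on a wild-type chromosome,
    or the entire trapping-cassette insertion on a tm1a/tm1c chromosome.
    ``len(product) == len(allele) + len(vector) + len(copied gap)``.
    """
    if vector.is_circular:
        raise MustLinearizeError(f"vector {vector.id} must be linearized first")
    arm5_f = vector.find(kind="homology_arm", label="arm5")
    arm3_f = vector.find(kind="homology_arm", label="arm3")
    if not arm5_f or not arm3_f:
        raise NoIntegrationError(f"vector {vector.id} lacks annotated homology arms")
    arm5 = vector.feature_seq(arm5_f[0])
    arm3 = vector.feature_seq(arm3_f[0])
    a5 = _find_subseq(allele_seq.residues, arm5)
    a3 = _find_subseq(allele_seq.residues, arm3)
    if a5 < 0 or a3 < 0 or a3 < a5 + len(arm5):
        raise NoIntegrationError(
            f"homology arms of {vector.id} do not match allele {allele_seq.id}")

    # re-circularize the vector conceptually: rotate so arm5 leads; the PmeI
    # half-sites at the molecule ends rejoin into one intact site.
    v5 = vector.find(kind="homology_arm", label="arm5")[0]
    circ = AnnotatedSequence(vector.residues, "circular", vector.features, vector.id)
    rot = circ.rotate(v5.start).linearized_at(0, id=f"{vector.id}_rot")
    r5 = rot.find(kind="homology_arm", label="arm5")[0]
    r3 = rot.find(kind="homology_arm", label="arm3")[0]

    template_gap = allele_seq.slice(a5 + len(arm5), a3, id="gap_copy") \
        if a3 > a5 + len(arm5) else AnnotatedSequence("", id="gap_copy")
    copy1 = concat([rot.slice(0, r3.start), template_gap,
                    rot.slice(r3.start, len(rot))], id="copy1_and_trap")
    product = concat(
        [allele_seq.slice(0, a5) if a5 > 0 else AnnotatedSequence("", id="f5"),
         copy1,
         allele_seq.slice(a5, len(allele_seq))],
        id=f"{allele_seq.id}_tm2")
    _log_event("integrate_insertion_vector", allele=allele_seq.id,
               vector=vector.id, gap_copied=len(template_gap),
               product_len=len(product))
    return product


def random_integrate(genome_flank: AnnotatedSequence,
                     vector: AnnotatedSequence, seed: int) -> AnnotatedSequence:
    """Blunt end-joining of the linear vector at a seeded-random position.

    No gap repair occurs, so the gap region (and the ex5 primer site it
    carries) is absent from the inserted copy.
    """
    import numpy as np

    if vector.is_circular:
        raise MustLinearizeError(f"vector {vector.id} must be linearized first")
    rng = np.random.default_rng(seed)
    pos = int(rng.integers(0, len(genome_flank) + 1))
    left = genome_flank.slice(0, pos) if pos > 0 else AnnotatedSequence("", id="l")
    right = genome_flank.slice(pos, len(genome_flank)) \
        if pos < len(genome_flank) else AnnotatedSequence("", id="r")
    product = concat([left, vector, right], id=f"{genome_flank.id}_randint")
    _log_event("random_integrate", genome=genome_flank.id, vector=vector.id,
               position=pos, product_len=len(product))
    return product
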