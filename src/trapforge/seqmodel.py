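"""Annotated-sequence data model.

Everything downstream — Gateway exchange, Cre/Flp excision, insertion
targeting, in-silico PCR — operates on :class:`AnnotatedSequence`: a linear
or circular DNA string decorated with typed, stranded features.  Coordinates
are 0-based half-open internally; the I/O layer converts to and from the
1-based inclusive convention of GenBank/GFF3.

Edits never truncate features silently: a feature wholly inside a retained
segment is remapped, a feature spanning an edit boundary is dropped and the
drop is logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .errors import (
    CoordinateError,
    DegenerateCutError,
    EmptyTranscriptError,
    InvalidMotifError,
)

logger = logging.getLogger(__name__)

#: IUPAC degenerate nucleotide codes -> set of concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

FEATURE_KINDS = frozenset({
    "exon", "cds_segment", "critical_exon", "homology_arm", "recomb_site",
    "restriction_site", "cassette", "primer_site", "promoter", "polyA",
    "splice_acceptor", "origin", "marker",
})


def revcomp(residues: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a sequence.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.  On circular
    sequences an interval may wrap the origin; it is stored with
    ``end = end mod L`` and ``wraps=True``, and its length is computed
    modulo the sequence length.
    """

    start: int
    end: int
    strand: str = "+"
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.wraps and self.start >= self.end:
            raise ValueError(f"empty interval ({self.start}, {self.end})")

    def length(self, seq_len: int | None = None) -> int:
        if self.wraps:
            if seq_len is None:
                raise ValueError("wrapped interval needs the sequence length")
            return (self.end - self.start) % seq_len
        return self.end - self.start

    def shift(self, offset: int) -> "Interval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class Feature:
    """A typed annotation on an :class:`AnnotatedSequence`.

    ``recomb_site`` features must carry a ``site_subtype`` qualifier
    (attL1..attB4, loxP, FRT, ...); ``cassette`` and ``marker`` features must
    carry ``marker_name``.
    """

    label: str
    kind: str
    interval: Interval
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "recomb_site" and "site_subtype" not in self.qualifiers:
            raise ValueError(f"recomb_site feature {self.label!r} lacks site_subtype")
        if self.kind in {"cassette", "marker"} and "marker_name" not in self.qualifiers:
            raise ValueError(f"{self.kind} feature {self.label!r} lacks marker_name")

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    def shift(self, offset: int) -> "Feature":
        return replace(self, interval=self.interval.shift(offset))


class AnnotatedSequence:
    """DNA residues + topology + features; the substrate of every operation."""

    def __init__(
        self,
        residues: str,
        topology: str = "linear",
        features: list[Feature] | None = None,
        id: str = "seq",
    ):
        residues = residues.upper()
        if re.search("[^ACGTN]", residues):
            bad = re.search("[^ACGTN]", residues).group()
            raise ValueError(f"non-DNA character {bad!r} in residues of {id!r}")
        if topology not in {"linear", "circular"}:
            raise ValueError(f"topology must be linear or circular, got {topology!r}")
        self.residues = residues
        self.topology = topology
        self.id = id
        self.features: list[Feature] = []
        for f in features or []:
            self.add_feature(f)

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.residues)

    def __repr__(self) -> str:
        return (f"AnnotatedSequence({self.id!r}, {len(self)} nt, "
                f"{self.topology}, {len(self.features)} features)")

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def add_feature(self, feat: Feature) -> None:
        L = len(self)
        iv = feat.interval
        if iv.wraps:
            if not self.is_circular:
                raise CoordinateError(f"wrapped feature {feat.label!r} on linear sequence")
            if not (0 <= iv.start < L and 0 <= iv.end <= L):
                raise CoordinateError(f"feature {feat.label!r} outside sequence bounds")
        elif not (0 <= iv.start < iv.end <= L):
            raise CoordinateError(
                f"feature {feat.label!r} ({iv.start},{iv.end}) outside [0,{L})")
        self.features.append(feat)

    def feature_seq(self, feat: Feature) -> str:
        iv = feat.interval
        if iv.wraps:
            s = self.residues[iv.start:] + self.residues[:iv.end]
        else:
            s = self.residues[iv.start:iv.end]
        return revcomp(s) if iv.strand == "-" else s

    def find(self, kind: str | None = None, label: str | None = None,
             subtype: str | None = None, marker: str | None = None) -> list[Feature]:
        """Features filtered by kind/label/site_subtype/marker_name, sorted by start."""
        out = []
        for f in self.features:
            if kind is not None and f.kind != kind:
                continue
            if label is not None and f.label != label:
                continue
            if subtype is not None and f.qualifiers.get("site_subtype") != subtype:
                continue
            if marker is not None and f.qualifiers.get("marker_name") != marker:
                continue
            out.append(f)
        return sorted(out, key=lambda f: (f.start, f.end))

    def copy(self, id: str | None = None) -> "AnnotatedSequence":
        return AnnotatedSequence(self.residues, self.topology,
                                 list(self.features), id or self.id)

    # -- geometry ----------------------------------------------------------

    def slice(self, start: int, end: int, id: str | None = None) -> "AnnotatedSequence":
        """Linear sub-sequence [start, end); features wholly inside are remapped,
        boundary-spanning features are dropped and logged."""
        if not (0 <= start < end <= len(self)):
            raise CoordinateError(f"slice ({start},{end}) outside [0,{len(self)}]")
        feats = []
        for f in self.features:
            if f.interval.wraps:
                logger.info("dropping wrapped feature %s in slice of %s", f.label, self.id)
                continue
            if f.start >= start and f.end <= end:
                feats.append(f.shift(-start))
            elif f.end <= start or f.start >= end:
                continue
            else:
                logger.info("dropping boundary-spanning feature %s (%d,%d) in slice of %s",
                            f.label, f.start, f.end, self.id)
        return AnnotatedSequence(self.residues[start:end], "linear", feats,
                                 id or f"{self.id}[{start}:{end}]")

    def rotate(self, origin: int, id: str | None = None) -> "AnnotatedSequence":
        """Rotate a circular sequence so position ``origin`` becomes 0."""
        if not self.is_circular:
            raise ValueError("rotate only applies to circular sequences")
        L = len(self)
        origin %= L
        feats = []
        for f in self.features:
            iv = f.interval
            s = (iv.start - origin) % L
            e = (iv.end - origin) % L
            if e == 0 and iv.length(L) > 0:
                e = L  # feature ends exactly at the new junction
            wraps = s >= e  # a plain feature may wrap the new origin
            feats.append(replace(f, interval=replace(iv, start=s, end=e % L if wraps else e,
                                                     wraps=wraps)))
        return AnnotatedSequence(self.residues[origin:] + self.residues[:origin],
                                 "circular", feats, id or self.id)

    def reverse_complement(self, id: str | None = None) -> "AnnotatedSequence":
        L = len(self)
        feats = []
        flip = {"+": "-", "-": "+"}
        for f in self.features:
            iv = f.interval
            if iv.wraps:
                ns, ne = (L - iv.end) % L, (L - iv.start) % L
                wraps = True
            else:
                ns, ne = L - iv.end, L - iv.start
                wraps = False
            feats.append(replace(
                f, interval=Interval(ns, ne, flip[iv.strand], wraps)))
        return AnnotatedSequence(revcomp(self.residues), self.topology, feats,
                                 id or self.id)

    def linearized_at(self, pos: int, id: str | None = None) -> "AnnotatedSequence":
        """Open a circular sequence at ``pos`` (blunt); length unchanged."""
        rot = self.rotate(pos, id=id)
        feats = []
        for f in rot.features:
            if f.interval.wraps:
                logger.info("dropping feature %s spanning the opening point of %s",
                            f.label, self.id)
                continue
            feats.append(f)
        return AnnotatedSequence(rot.residues, "linear", feats, id or self.id)


def concat(parts: list[AnnotatedSequence], id: str = "concat",
           topology: str = "linear") -> AnnotatedSequence:
    """Concatenate linear annotated sequences, remapping every feature."""
    residues = []
    feats: list[Feature] = []
    offset = 0
    for p in parts:
        if p.is_circular:
            raise ValueError("cannot concatenate circular sequences")
        residues.append(p.residues)
        for f in p.features:
            feats.append(f.shift(offset))
        offset += len(p)
    return AnnotatedSequence("".join(residues), topology, feats, id)


# -- motif scanning --------------------------------------------------------

def _motif_regex(motif: str) -> re.Pattern:
    if len(motif) < 4:
        raise InvalidMotifError(f"motif {motif!r} shorter than 4 nt")
    pieces = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise InvalidMotifError(f"non-IUPAC character {ch!r} in motif {motif!r}")
        opts = IUPAC[ch]
        pieces.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(pieces))


def scan_motif(seq: AnnotatedSequence, motif: str,
               both_strands: bool = False) -> list[Interval]:
    """All occurrences of an IUPAC-degenerate motif.

    Circular sequences are scanned across the junction.  With
    ``both_strands`` set, minus-strand hits are reported on plus-strand
    coordinates with strand '-'; a palindromic motif is reported once per
    position.
    """
    pat = _motif_regex(motif)
    m = len(motif)
    L = len(seq)
    text = seq.residues
    limit = L
    if seq.is_circular and L >= m:
        text = text + text[: m - 1]  # cover the junction
    hits: dict[tuple[int, int], str] = {}
    pos = 0
    while True:
        match = pat.search(text, pos)
        if match is None:
            break
        s = match.start()
        if s < limit:
            e = s + m
            hits[(s % max(L, 1), e % L if seq.is_circular and e > L else e)] = "+"
        pos = s + 1
    if both_strands:
        rc_hits = scan_motif(seq.reverse_complement(), motif, both_strands=False)
        for iv in rc_hits:
            s = (L - iv.end) % L if iv.wraps else L - iv.end
            e = (L - iv.start) % L if iv.wraps else L - iv.start
            key = (s, e)
            if key not in hits:  # palindrome dedup
                hits[key] = "-"
    out = []
    for (s, e), strand in hits.items():
        wraps = seq.is_circular and (e <= s)
        out.append(Interval(s, e if not wraps else e % L, strand, wraps))
    return sorted(out, key=lambda iv: (iv.start, iv.end))


# -- editing ---------------------------------------------------------------

def excise_segment(seq: AnnotatedSequence, cut_left: int,
                   cut_right: int) -> tuple[AnnotatedSequence, AnnotatedSequence]:
    """Cut at two offsets; return (remainder, excised).

    Linear input: the excised piece is ``[cut_left, cut_right)`` and both
    products are linear.  Circular input: both products are circular and the
    cuts may wrap the origin.  Lengths always partition the input.
    """
    if cut_left == cut_right:
        raise DegenerateCutError("cut offsets coincide")
    L = len(seq)
    for c in (cut_left, cut_right):
        if not (0 <= c <= L):
            raise CoordinateError(f"cut offset {c} outside [0,{L}]")
    if seq.is_circular:
        rot = seq.rotate(cut_left)
        span = (cut_right - cut_left) % L
        excised = rot.slice(0, span, id=f"{seq.id}_excised")
        remainder = rot.slice(span, L, id=f"{seq.id}_remainder")
        excised.topology = "circular"
        remainder.topology = "circular"
        return remainder, excised
    if cut_left > cut_right:
        cut_left, cut_right = cut_right, cut_left
    excised = seq.slice(cut_left, cut_right, id=f"{seq.id}_excised")
    left = seq.slice(0, cut_left, id=f"{seq.id}_left") if cut_left > 0 else None
    right = seq.slice(cut_right, L, id=f"{seq.id}_right") if cut_right < L else None
    parts = [p for p in (left, right) if p is not None]
    remainder = concat(parts, id=f"{seq.id}_remainder") if parts else \
        AnnotatedSequence("", id=f"{seq.id}_remainder")
    return remainder, excised


# -- transcript splicing ---------------------------------------------------

def splice_transcript(seq: AnnotatedSequence,
                      exons: list[Interval] | None = None) -> AnnotatedSequence:
    """Spliced mRNA from the exon features of a locus.

    Exons are concatenated in transcription order.  If a trap — a
    ``splice_acceptor`` followed by a ``cassette`` with a downstream
    ``polyA`` — lies between two exons (or after the last exon), splicing
    terminates there: the message is the upstream exons plus the cassette
    segment from the splice acceptor's 3' end through the polyA.
    """
    if exons is None:
        exons = [f.interval for f in seq.find(kind="exon")]
    exons = sorted(exons, key=lambda iv: iv.start)
    if not exons:
        raise EmptyTranscriptError(f"no exons on {seq.id}")
    strand = exons[0].strand
    if strand == "-":
        # mirror to the plus strand and recurse: identical mRNA by construction
        mirrored = seq.reverse_complement()
        return splice_transcript(mirrored)

    acceptors = seq.find(kind="splice_acceptor")
    polyas = seq.find(kind="polyA")

    def trap_between(lo: int, hi: int):
        """First (acceptor, polyA) trap with acceptor in [lo, hi)."""
        for sa in acceptors:
            if lo <= sa.start < hi:
                for pa in polyas:
                    if pa.start >= sa.end and pa.end <= hi:
                        return sa, pa
        return None

    pieces = []
    feats: list[Feature] = []
    offset = 0
    L = len(seq)
    for i, ex in enumerate(exons):
        pieces.append(seq.residues[ex.start:ex.end])
        for f in seq.features:
            if f.start >= ex.start and f.end <= ex.end and f.kind != "exon":
                feats.append(f.shift(offset - ex.start))
        offset += ex.length()
        nxt = exons[i + 1].start if i + 1 < len(exons) else L
        trap = trap_between(ex.end, nxt)
        if trap is not None:
            sa, pa = trap
            seg_start, seg_end = sa.end, pa.end
            pieces.append(seq.residues[seg_start:seg_end])
            for f in seq.features:
                if f.start >= seg_start and f.end <= seg_end:
                    feats.append(f.shift(offset - seg_start))
            offset += seg_end - seg_start
            break
    return AnnotatedSequence("".join(pieces), "linear", feats,
                             id=f"{seq.id}_mRNA")
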