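"""Standard-format I/O: GenBank and FASTA for annotated sequences, GFF3 for
gene models.

Internal coordinates are 0-based half-open; GenBank and GFF3 are written and
read 1-based inclusive.  The GenBank round trip is lossless for residues,
topology and features (feature kind and qualifiers are carried in
qualifiers, since some kind names exceed the GenBank feature-key width).
"""

from __future__ import annotations

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .alleles import GeneModel
from .errors import ParseError
from .seqmodel import AnnotatedSequence, Feature, Interval

_GB_KEY = {"restriction_site": "misc_feature", "splice_acceptor": "misc_feature",
           "cds_segment": "CDS", "critical_exon": "exon",
           "homology_arm": "misc_feature", "recomb_site": "misc_recomb",
           "cassette": "misc_feature", "primer_site": "primer_bind",
           "origin": "rep_origin", "marker": "gene"}


def to_seqrecord(seq: AnnotatedSequence) -> SeqRecord:
    rec = SeqRecord(Seq(seq.residues), id=seq.id, name=seq.id[:16] or "seq",
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = seq.topology
    for f in seq.features:
        iv = f.interval
        quals = {"label": [f.label], "tf_kind": [f.kind]}
        for k, v in f.qualifiers.items():
            quals[k] = [str(v)]
        if iv.wraps:
            quals["tf_wraps"] = ["1"]
        strand = 1 if iv.strand == "+" else -1
        loc = FeatureLocation(iv.start, iv.end if not iv.wraps else len(seq),
                              strand)
        rec.features.append(SeqFeature(loc, type=_GB_KEY.get(f.kind, f.kind),
                                       qualifiers=quals))
    return rec


def from_seqrecord(rec: SeqRecord) -> AnnotatedSequence:
    topology = rec.annotations.get("topology", "linear")
    feats = []
    for sf in rec.features:
        quals = {k: v[0] for k, v in sf.qualifiers.items()}
        kind = quals.pop("tf_kind", None)
        if kind is None:
            continue  # foreign annotation; keep residues only
        label = quals.pop("label", kind)
        quals.pop("tf_wraps", None)
        if "frame_phase" in quals:
            quals["frame_phase"] = int(quals["frame_phase"])
        strand = "+" if (sf.location.strand or 1) >= 0 else "-"
        feats.append(Feature(label, kind,
                             Interval(int(sf.location.start),
                                      int(sf.location.end), strand), quals))
    return AnnotatedSequence(str(rec.seq), topology, feats, id=rec.id)


def write_genbank(seq: AnnotatedSequence, path: str) -> None:
    SeqIO.write([to_seqrecord(seq)], path, "genbank")


def read_genbank(path: str) -> AnnotatedSequence:
    try:
        rec = next(SeqIO.parse(path, "genbank"))
    except (StopIteration, ValueError) as exc:
        raise ParseError(f"malformed GenBank record in {path}: {exc}") from exc
    return from_seqrecord(rec)


def write_fasta(seq: AnnotatedSequence, path: str) -> None:
    rec = SeqRecord(Seq(seq.residues), id=seq.id, description=seq.topology)
    SeqIO.write([rec], path, "fasta")


def read_fasta(path: str) -> AnnotatedSequence:
    try:
        rec = next(SeqIO.parse(path, "fasta"))
    except (StopIteration, ValueError) as exc:
        raise ParseError(f"malformed FASTA record in {path}: {exc}") from exc
    return AnnotatedSequence(str(rec.seq), "linear", [], id=rec.id)


# -- GFF3 ------------------------------------------------------------------

def write_gff3(gene: GeneModel, seqid: str, path: str) -> None:
    """Gene model as GFF3 (1-based inclusive)."""
    gid = gene.gene_id
    span = (min(e.start for e in gene.exons) + 1, max(e.end for e in gene.exons))
    lines = ["##gff-version 3"]

    def row(ftype, start, end, attrs):
        return "\t".join([seqid, "trapforge", ftype, str(start), str(end),
                          ".", gene.strand, ".", attrs])

    lines.append(row("gene", *span, f"ID=gene:{gid}"))
    lines.append(row("mRNA", *span, f"ID=tx:{gid};Parent=gene:{gid}"))
    for i, e in enumerate(gene.exons, 1):
        attrs = f"ID=exon:{gid}.{i};Parent=tx:{gid}"
        if i - 1 == gene.critical_exon_index:
            attrs += ";critical_exon=true"
        lines.append(row("exon", e.start + 1, e.end, attrs))
    for i, c in enumerate(gene.cds, 1):
        lines.append(row("CDS", c.start + 1, c.end, f"ID=cds:{gid}.{i};Parent=tx:{gid}"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str) -> GeneModel:
    """Parse one gene model from GFF3 via gffutils (converts to 0-based
    half-open internally)."""
    try:
        db = gffutils.create_db(path, ":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"malformed GFF3 in {path}: {exc}") from exc
    genes = list(db.features_of_type("gene"))
    if not genes:
        raise ParseError(f"no gene record in {path}")
    g = genes[0]
    gid = g.id.split(":", 1)[-1]
    exons, cds, ce_index = [], [], 2
    for i, e in enumerate(db.children(g, featuretype="exon", order_by="start")):
        exons.append(Interval(e.start - 1, e.end, g.strand))
        if e.attributes.get("critical_exon", ["false"])[0] == "true":
            ce_index = i
    for c in db.children(g, featuretype="CDS", order_by="start"):
        cds.append(Interval(c.start - 1, c.end, g.strand))
    if not exons:
        raise ParseError(f"gene {gid} has no exons in {path}")
    return GeneModel(gene_id=gid, strand=g.strand, exons=exons, cds=cds,
                     critical_exon_index=ce_index)
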