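"""Canonical vector parts: recombination sites, marker ORFs, trap cassettes.

Site sequences the community standardizes on (34 nt loxP, 34 nt minimal FRT,
the 8 nt PmeI recognition site) are used verbatim.  Marker open reading
frames (hygro, GFP, lacZ, neo, ...) are synthetic stand-ins: deterministic
pseudo-ORFs that are stop-free in frame 0 and contain stop codons in the two
shifted frames, which is the only property the simulation relies on (frame
selection, truncation prediction, fusion translation).  att sites are typed
features realized as fixed 25 nt placeholder cores, since recombination is
driven by feature matching, not sequence homology.

All sequences here are generated once per import from a fixed RNG stream and
are therefore identical across processes.
"""

from __future__ import annotations

import numpy as np

from .seqmodel import AnnotatedSequence, Feature, Interval, revcomp

PMEI_SITE = "GTTTAAAC"          # blunt cutter, cleaves GTTT/AAAC
PMEI_CUT_OFFSET = 4
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"      # 34 nt, canonical
FRT = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"       # 34 nt minimal FRT

STOP_CODONS = ("TAA", "TAG", "TGA")

_CODONS = [a + b + c
           for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in STOP_CODONS]

_FORBIDDEN = (PMEI_SITE, LOXP, FRT)


def _clean(seq: str) -> bool:
    return all(m not in seq and m not in revcomp(seq) for m in _FORBIDDEN)


def random_dna(rng: np.random.Generator, n: int,
               forbid: tuple[str, ...] = (PMEI_SITE,)) -> str:
    """Random DNA of length ``n`` free of the forbidden motifs (both strands)."""
    bases = np.array(list("ACGT"))
    for _ in range(200):
        s = "".join(rng.choice(bases, size=n))
        if all(m not in s and m not in revcomp(s) for m in forbid):
            return s
        # patch occurrences instead of full rejection for long sequences
        for m in forbid:
            for probe in (m, revcomp(m)):
                while probe in s:
                    i = s.index(probe)
                    repl = "".join(rng.choice(bases, size=len(probe)))
                    s = s[:i] + repl + s[i + len(probe):]
        if all(m not in s and m not in revcomp(s) for m in forbid):
            return s
    raise RuntimeError("could not generate motif-free sequence")


def random_orf(rng: np.random.Generator, n_codons: int,
               terminal_stop: bool = False) -> str:
    """Pseudo-ORF: stop-free in frame 0, with stops present in frames +1/+2.

    Used for synthetic marker CDSs so that brute-force three-frame
    translation singles out the designed frame.
    """
    for _ in range(100):
        body = "".join(rng.choice(_CODONS, size=n_codons - (1 if terminal_stop else 0)))
        if terminal_stop:
            body += "TAA"
        shifted_stopped = all(
            any(body[i:i + 3] in STOP_CODONS for i in range(off, len(body) - 2, 3))
            for off in (1, 2))
        if shifted_stopped and _clean(body):
            return body
    raise RuntimeError("could not generate pseudo-ORF")


_rng = np.random.default_rng(797003)

# 25 nt placeholder cores for Gateway sites; one core per index, shared by
# the L/R/B/P flavours so relabelling conserves residues exactly.
ATT_CORES = {i: random_dna(_rng, 25, _FORBIDDEN) for i in (1, 2, 3, 4)}

# Marker ORF lengths (nt, incl. stop) chosen near the real genes so that
# cassette and amplicon sizes land in the published ranges.
_MARKER_CODONS = {
    "lacZ": 1023, "neo": 267, "hygro": 341, "GFP": 239,
    "rpsL": 124, "kan": 271, "cat": 219, "zeo": 124, "amp": 286, "nat": 191,
}
MARKER_ORFS = {name: random_orf(_rng, n, terminal_stop=(name not in ("lacZ", "hygro", "GFP")))
               for name, n in _MARKER_CODONS.items()}

SPLICE_ACCEPTOR = random_dna(_rng, 150, _FORBIDDEN)   # En2-style SA, synthetic
T2A = random_orf(_rng, 22)                            # 2A-like ribosome-skip element
POLYA = random_dna(_rng, 240, _FORBIDDEN)             # SV40-style pA, synthetic
ORIGIN = random_dna(_rng, 600, _FORBIDDEN)

LAR3_SITE = MARKER_ORFS["lacZ"][900:920]              # reverse primer lands in lacZ
HYGRO1R_SITE = MARKER_ORFS["hygro"][450:470]          # reverse primer lands in hygro


def site_feature(subtype: str, start: int, label: str | None = None,
                 strand: str = "+") -> Feature:
    seqs = {"loxP": LOXP, "FRT": FRT, "PmeI": PMEI_SITE}
    n = len(seqs[subtype]) if subtype in seqs else 25
    kind = "restriction_site" if subtype == "PmeI" else "recomb_site"
    quals = {"site_subtype": subtype}
    return Feature(label or subtype, kind, Interval(start, start + n, strand), quals)


class PartBlock:
    """Helper accumulating residues + features at a running offset."""

    def __init__(self):
        self.parts: list[str] = []
        self.features: list[Feature] = []
        self.offset = 0

    def add(self, residues: str, *feats_at_zero: Feature) -> int:
        """Append residues; any features given are shifted by current offset."""
        start = self.offset
        self.parts.append(residues)
        for f in feats_at_zero:
            self.features.append(f.shift(start))
        self.offset += len(residues)
        return start

    def add_site(self, subtype: str, label: str | None = None) -> int:
        seqs = {"loxP": LOXP, "FRT": FRT, "PmeI": PMEI_SITE}
        core = seqs.get(subtype, ATT_CORES[int(subtype[-1])])
        return self.add(core, site_feature(subtype, 0, label))

    def add_marker(self, name: str, label: str | None = None) -> int:
        orf = MARKER_ORFS[name]
        return self.add(orf, Feature(label or name, "marker",
                                     Interval(0, len(orf)), {"marker_name": name}))

    def add_primer_site(self, name: str, residues: str, strand: str = "+") -> int:
        return self.add(residues, Feature(name, "primer_site",
                                          Interval(0, len(residues), strand)))

    def seq(self, id: str, topology: str = "linear") -> AnnotatedSequence:
        return AnnotatedSequence("".join(self.parts), topology, self.features, id)


def hyg_gfp_cassette(frame_phase: int) -> AnnotatedSequence:
    """One reading-frame variant of the hygromycin-GFP splice-trap cassette.

    Layout: splice acceptor | phase adapter | 2A | hygro | 2A | GFP | stop |
    polyA.  The phase adapter length is congruent to ``-frame_phase mod 3``
    so that a fusion joined after an exon of end phase ``frame_phase`` reads
    the trap ORF in frame.
    """
    if frame_phase not in (0, 1, 2):
        raise ValueError("frame_phase must be 0, 1 or 2")
    b = PartBlock()
    sa_start = b.add(SPLICE_ACCEPTOR,
                     Feature("En2_SA", "splice_acceptor", Interval(0, len(SPLICE_ACCEPTOR))))
    # Adapter starts with CC so the hybrid junction codon (exon overhang +
    # adapter prefix) can never form a stop, whatever the exon ends with.
    adapter = "CCGGCGCAG"[: 3 + (3 - frame_phase) % 3]   # 3..5 nt
    b.add(adapter)
    b.add(T2A)
    hyg_start = b.add(MARKER_ORFS["hygro"],
                      Feature("hygro", "marker",
                              Interval(0, len(MARKER_ORFS["hygro"])), {"marker_name": "hygro"}))
    b.add(T2A)
    b.add(MARKER_ORFS["GFP"],
          Feature("GFP", "marker", Interval(0, len(MARKER_ORFS["GFP"])),
                  {"marker_name": "GFP"}))
    b.add("TAA")
    b.add(POLYA, Feature("pA", "polyA", Interval(0, len(POLYA))))
    cas = b.seq(f"hygGFP_F{frame_phase}")
    # hygro_1R reverse-primer site inside the hygro ORF
    cas.add_feature(Feature("hygro_1R", "primer_site",
                            Interval(hyg_start + 450, hyg_start + 470, "-")))
    cas.add_feature(Feature(f"hygGFP_F{frame_phase}", "cassette",
                            Interval(0, len(cas)),
                            {"marker_name": "hygro-GFP", "frame_phase": frame_phase}))
    del sa_start
    return cas


def beta_geo_cassette() -> AnnotatedSequence:
    """Promoterless lacZ-neo (beta-geo) splice-trap cassette of the
    knockout-first allele: SA | lacZ | 2A | neo | stop | pA, ~5.0 kb."""
    b = PartBlock()
    b.add(SPLICE_ACCEPTOR,
          Feature("En2_SA", "splice_acceptor", Interval(0, len(SPLICE_ACCEPTOR))))
    b.add("GCC")
    lz_start = b.add(MARKER_ORFS["lacZ"],
                     Feature("lacZ", "marker", Interval(0, len(MARKER_ORFS["lacZ"])),
                             {"marker_name": "lacZ"}))
    b.add(T2A)
    b.add(MARKER_ORFS["neo"],
          Feature("neo", "marker", Interval(0, len(MARKER_ORFS["neo"])),
                  {"marker_name": "neo"}))
    b.add(POLYA, Feature("pA", "polyA", Interval(0, len(POLYA))))
    # pad with inert spacer so the cassette is ~5.0 kb, matching the size
    # signature that separates the tm1a and tm1c genotyping amplicons
    pad = 5000 - b.offset
    if pad > 0:
        b.add(random_dna(np.random.default_rng(424242), pad, _FORBIDDEN))
    cas = b.seq("beta_geo")
    cas.add_feature(Feature("LAR_3", "primer_site",
                            Interval(lz_start + 900, lz_start + 920, "-")))
    cas.add_feature(Feature("beta_geo", "cassette", Interval(0, len(cas)),
                            {"marker_name": "beta-geo"}))
    return cas


def cassette_library() -> dict[int, AnnotatedSequence]:
    """The three reading-frame variants of the hygromycin-GFP trap."""
    return {p: hyg_gfp_cassette(p) for p in (0, 1, 2)}
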