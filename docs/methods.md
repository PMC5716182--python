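# Methods

This note documents the models, defaults and numerical conventions behind
`trapforge`, and what the synthetic fixtures do and do not capture.

## Coordinate and sequence conventions

Internally everything is 0-based half-open on the plus strand; GenBank and
GFF3 are converted to/from 1-based inclusive at the I/O boundary. Circular
molecules store wrapped intervals as `(start, end mod L)` with a wrap flag.
Edits never truncate a feature silently: features wholly inside a retained
segment are remapped, features spanning an edit boundary are dropped with a
logged reason. Every recombination operation partitions its input residues
(the one shared site copy of a Cre/Flp excision is accounted to the excised
circle; gap repair adds exactly the copied template span).

Recombination sites are typed features, not sequence motifs. loxP and the
minimal FRT use their community-standard 34 nt sequences; Gateway att sites
are realized as fixed 25 nt placeholder cores shared across the L/R/B/P
flavours of each index, so relabelling during exchange conserves residues
exactly. This is deliberate: the exchange contract (which segment replaces
which) is what the method depends on, not att sequence chemistry.
Inverted-repeat Cre/Flp substrates raise an error rather than inverting —
every construct in scope uses direct repeats, and silent inversion would
mask fixture bugs.

## Vector assembly

The Intermediate Vector fixture is laid out as
`arm5 (G5..U3) | attR1 | stuffer | attR2 | critical region (U3..D5) | rpsL |
loxP | arm3 (D5..G3) | attR3 | backbone (ori, zeo, amp) | attR4`, circular,
~14.8 kb — the ~15 kb size expectation is treated as a QC warning with
±30 % tolerance, not an error. The adaptor donor contributes
`PmeI | spacer | loxP` between attL1/attL2 (~0.35 kb payload); placing the
PmeI site distal to the loxP (hence distal to the critical exon) is a
convention choice, since only the loxP and gap contracts are observable
downstream. The trap donor contributes the cassette plus kan and an origin
between attL3/attL4, so the exchanged product is selectable on
kan/streptomycin (rpsL loss after the bacterial Cre step restores
streptomycin resistance); the chloramphenicol marker stays on the donor
backbone, which makes unreacted donor the expected background colony class.

The hygromycin-GFP cassette is `SA | phase adapter | 2A | hygro | 2A | GFP |
stop | pA`, padded to 3.2 kb; the β-geo cassette is `SA | lacZ | 2A | neo |
pA` padded to 5.0 kb. The phase adapter begins with `CC` so the hybrid
junction codon (exon overhang + adapter prefix) can never form a stop
regardless of the upstream exon sequence. Marker ORFs are synthetic
pseudo-ORFs: deterministic codon strings, stop-free in frame 0 and
guaranteed to contain stops in both shifted frames — the only properties
the frame rule, truncation prediction and translation oracles rely on.

## Gap repair and the cis contract

The insertion vector is linearized at the unique PmeI cut inside its
homology region; integration re-circularizes it conceptually at that cut,
fills the gap by repair synthesis from the chromosomal template, and
inserts the whole molecule at the crossover, duplicating the homology. The
repaired (vector-derived) copy is placed first, carrying the adaptor loxP
at the repair junction; junction microstructure beyond that (PmeI
half-sites, attB remnants) is not modelled further.

One modelling decision matters for the selection logic: repair synthesis
copies **whatever the template holds between the two arms**, not an
idealized wild-type gap. On a wild-type chromosome that is the critical
exon region (restoring the ex5 site — the basis of the gap-repair PCR
screen). On a tm1a chromosome it is the entire β-geo insertion, which puts
a splice trap upstream of the hygro cassette in the integrated product —
this is exactly why in-cis targeting of tm1a is never
hygromycin-recoverable while in-cis targeting of tm1c is (and must then be
caught by the cis/trans junction PCR). A "copy the wild-type gap only"
model would get the cis selection contract wrong.

Random integration is blunt end-joining without gap repair; only its
PCR-negativity matters. A random-integration *clone* is modelled as two
chromosomes — the intact target locus and an unrelated flank carrying the
vector — because amplification cannot bridge molecules; this is what makes
the ex5/hygro_1R screen robustly negative.

## Expression and selection logic

The transcript is walked from the promoter; the first splice acceptor +
cassette + polyA between retained exons terminates the message. β-geo
reporters are modelled frame-independent (internal translation entry) and
require locus expression at or above 1 % of the transferrin-receptor
reference (the documented floor for targeted trapping; configurable).
Hygro/GFP additionally require the cassette's frame variant to equal the
end phase at the junction. Truncation products are
`floor(upstream coding nt / 3)` residues for trapped alleles, or
translation to the first stop for critical-exon frameshifts; masses use the
110.5 Da average residue mass, which reproduces the published 353 aa →
39 kDa and 97 aa → 11 kDa conversions at nearest-integer rounding (the
published 172 aa → 20 kDa case evidently used the true residue composition;
this model gives 19 kDa there, and no test asserts otherwise).

Essentiality is a fixture-level ground-truth flag consumed by viability
(a line is inviable if the gene is essential and no allele makes full
protein): the simulator reproduces the *inference direction* of the
method — absence of recoverable bi-allelic clones — rather than inferring
essentiality from sequence.

## Workflow simulation

Protocols are ordered steps (`flp`, `electroporate`+`select`,
`screen_trans`, `knockin_creert2`, `induce_4oht`, `subclone`) applied to a
population of genotype fractions. Selection keeps every recoverable
outcome (including cis events into tm1c, at equal weight); `screen_trans`
is the explicit junction-PCR screen that removes them, mirroring lab
practice. Induction converts tm1c→tm1d per cell with probability
`1 − escaper_rate`, uninduced steps convert with `leak_rate`, both drawn as
binomial fractions over `n_cells` (default 10⁵) from the line's seed. The
reported escaper fraction is measured immediately after induction, before
any subcloning collapses it.

## Genotyping

Primer binding is exact-site lookup on `primer_site` features — placement
rules and amplicon structure are the published contract; thermodynamics is
out of scope. Expected band classes are computed from reference alleles at
design time, and calling inverts them at ±10 % size tolerance (long-range
PCR sizes are approximate). Call candidates are the allele pairs the
screening workflow can produce; tm1b is a valid state-machine transition
but not a screening intermediate, and the long-range assays cannot separate
it from tm1a at that tolerance, so it is not a candidate. A clone with no
bands at all is reported as inconsistent rather than called wild-type —
screened clones always carry at least one engineered allele, so an
all-absent pattern means a failed assay. The cis/trans junction assay is
intentionally all-vector-internal (both primers vector-specific) and is
exempt from the external-primer placement rule that governs the
targeting-detection assays. Screening summaries round percentages to one
decimal, average duplicate lines of a gene before gene-level statistics,
and count gene recovery over the heterozygous experimental rows.

## Synthetic fixtures: scope and calibration

A fixture locus is a five-exon expressed gene on ~14.3 kb: promoter +
exon 1 outside the homology region, exon 2 in the 5' arm (5 kb), the
critical exon (length never divisible by 3, so deletion frameshifts) in the
0.8 kb loxP-flankable region, exon 4 in the 3' arm (4.8 kb), exon 5
downstream, with the gf3 site 1 kb outside the 5' arm and ex5 inside the
gap region. Arm and cassette sizes were chosen once so the genotyping
amplicons land in the published size classes: gf3/LR ≈ 12.0 kb (tm1a) vs
7.0 kb (tm1c), ex5/hygro_1R ≈ 6.0 kb, cis junction ≈ 6.4 kb. The end phase
at the homology boundary is set exactly via the exon-2 length when a phase
target is requested. Generation is deterministic per seed (a bounded retry
loop, also seeded, regenerates the rare locus whose random background
collides with a forbidden motif), and homology arms are kept PmeI-free so
that planted extra sites are the *only* sites — planted-truth screening is
exact, not statistical.

The fixtures emulate the features the method reads: exon/intron structure,
reading-frame phase, expression level, site geometry, amplicon sizes. They
do not emulate mouse genome composition, repeat structure, recombination
efficiency or kinetics, double-crossover replacement targeting, or
cell-biology phenotypes (growth, differentiation, rescue). Passing tests
therefore validate the *logic* of the workflow — assembly, recombination
algebra, selection, screening — not wet-lab efficiencies; the published
per-gene targeting percentages enter only as data summarized by
`summarize_screen`, never as simulated outcomes.

## Problem sizes

Defaults used by the test suite and acceptance script, chosen as desk-scale
study conditions: 50-seed recombinase-algebra and 100-seed gap-repair
panels; a 1000-design PmeI panel at planting probability 0.115; the
genotype round trip over all reachable pairs on 10 loci; escaper statistics
over 10⁵ cells at rates 10⁻³–10⁻²; screening-table checks on the 24-row
reference tallies. The whole suite runs in well under a minute on one CPU.
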