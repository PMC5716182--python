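# trapforge

In-silico simulation of **bi-allelic "targeted trapping"** — the
second-allele gene-ablation strategy for mouse embryonic stem (ES) cells
built on IKMC "knockout-first" resources.

## The problem and who this is for

Knocking out both alleles of a gene in ES cells normally means two rounds of
targeting with two selection cassettes and a lot of screening. Targeted
trapping shortcuts this: a *promoterless* splice-trap cassette only confers
drug resistance when it lands in an expressed locus and splices in-frame to
the endogenous transcript, so correct integrations select themselves. The
workflow modelled here starts from a heterozygous "knockout-first" line
(*tm1a*/+) and converts the remaining wild-type allele to a trapped null
(*tm2*) with a **pI_hygGFP insertion vector**, giving constitutive
bi-allelic nulls — or, via Flp reversion and tamoxifen-inducible Cre, an
inducible conditional null (*tm1c*/*tm2* → *tm1d*/*tm2*).

`trapforge` implements every step of that workflow as code, exercisable
end-to-end on seeded synthetic loci: vector construction, recombination,
selection logic, genotyping and screening statistics. It is aimed at people
designing or teaching these workflows, and at anyone who wants executable,
testable semantics for conditional-allele engineering.

## The model

**Vector construction.** An IKMC-style Intermediate Vector (homology arms
`G5..U3` and `D5..G3` around a loxP-flanked "critical exon" region carrying
an rpsL counter-selection marker) is re-configured by a three-way Gateway
exchange: an adaptor module contributes a rare PmeI site and a loxP
upstream of the critical exon, and a hygromycin-GFP trap cassette
(SA–2A–hygro–2A–GFP–pA, in one of three reading frames) replaces the
plasmid backbone. Bacterial Cre then deletes the floxed critical exon +
rpsL (kan/streptomycin selects for the event), leaving a *gap* in the
genomic homology, and the vector is linearized at its unique PmeI site.
Designs whose homology region contains an extra PmeI site cannot be
linearized intact and are screened out up front.

**The frame rule.** The cassette variant is chosen so that
`frame_phase = (cumulative CDS length through the most 3' exon inside the
homology region) mod 3` — the trap ORF then reads in frame after splicing.

**Integration.** The linearized insertion (O-type) vector integrates by a
single crossover, duplicating the homology region around the trap cassette;
the missing critical-exon region is restored in the vector-derived copy by
**gap repair** from the chromosomal template. This regenerates the `ex5`
primer site *only* in correctly targeted alleles — random integrations lack
it and are PCR-negative.

**Selection logic.** Hygromycin resistance requires splicing from an
expressed locus in the matching frame. Integration *in cis* into the tm1a
allele copies the upstream β-geo trap along with the gap, which truncates
the message before the hygro cassette — so only bi-allelic (trans) events
survive selection, and recovery failure is the operational signature of an
ES-cell-essential gene.

**Allele states.** `wt`, `tm1a` (knockout-first), `tm1b` (Cre on tm1a),
`tm1c` (Flp reversion), `tm1d` (Cre on tm1c; frameshift null), `tm2`
(insertion trap), with a census validator per state and Cre/Flp modelled as
excision between direct repeats (Flp∘Cre ≡ Cre∘Flp on tm1a).

**Genotyping.** Four long-range PCR assays by exact-site lookup:
`gf3+LAR_3` (tm1a), `ex5+hygro_1R` (tm2, gap-repair dependent; ~6–7 kb),
`gf3+LR` (tm1a ~12 kb vs tm1c ~7 kb; silent on tm2), and
`R1_amp_F2+hygro_1R` (~6 kb junction product iff the two vectors are in
cis). Clone calling inverts the expected band maps at ±10 % size tolerance.

## Worked example

```console
$ trapforge build-vector --seed 3 --out-dir vector
final vector 13899 nt, frame 2; wrote vector/pI_hygGFP_Gene3.gb
```

The seeded fixture locus `Gene3` has end phase 2, so the frame-2 cassette
is selected; the finished vector carries exactly one loxP, zero Gateway
sites, no rpsL, and is opened at its blunt PmeI cut (13 899 nt).

```console
$ trapforge simulate-workflow --seed 3 --out-dir workflow
final population: {"tm1d/tm2": 1.0}
```

The trajectory written to `workflow/trajectory.json` shows the inducible
conditional route: `tm1a/+ → (Flp) tm1c/+ → (pI_hygGFP + hygromycin)
tm1c/tm2 and tm1c::tm2cis/+ → (cis/trans screen) tm1c/tm2 → (CreERT2,
4′OHT) tm1d/tm2`, with a residual escaper fraction of `0.00099` at the
default escaper rate of 10⁻³ — about 1 non-recombined cell per 1000.

```console
$ trapforge summarize --out-dir summary
{"max_pct": 100.0, "mean_pct": 79.6, "min_pct": 50.0, "n_genes": 9, ...}
```

This summarizes the package's reference screening tallies (wild-type
control electroporations for nine genes): an unweighted mean targeting
efficiency of 79.6 % (80 % to the nearest integer), ranging from 50 % to
100 %. Over the heterozygous experimental rows the same report counts 11
genes with recovered bi-allelic clones and 3 without (`Ddx27`, `Phf20`,
`Setdb1`) — the essentiality signal.

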