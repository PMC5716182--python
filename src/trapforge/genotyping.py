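"""Genotyping assay design, in-silico PCR, clone calling and screening
summaries.

The four canonical long-range PCR assays of the bi-allelic targeting
workflow:

* ``gf3 + LAR_3``       — knockout-first (tm1a/tm1b) detection: genomic
  forward primer external to the 5' arm, reverse primer in lacZ.
* ``ex5 + hygro_1R``    — tm2 detection: forward primer inside the gap
  region (present in the genome only after gap repair), reverse primer in
  hygro.  Random integrations are PCR-negative by construction.
* ``gf3 + LR``          — tm1a (~12 kb class) vs tm1c (~7 kb class);
  silent on tm2, whose template lacks the LR site.
* ``R1_amp_F2 + hygro_1R`` — cis/trans discrimination of double targeting.

Primer binding is exact-site lookup on ``primer_site`` features, which
survive every edit with remapped coordinates; thermodynamics is out of
scope.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import AlleleMap, CellLine, GeneModel, expression_outcome
from .errors import DataError, DesignError
from .seqmodel import AnnotatedSequence

logger = logging.getLogger(__name__)

#: fractional tolerance for matching an observed band to an expected class
SIZE_TOLERANCE = 0.10

LR_PCR_MAX_LEN = 15_000


@dataclass(frozen=True)
class Primer:
    """A named primer; binding is resolved per template by feature lookup."""

    name: str
    orientation: str            # '+' forward, '-' reverse
    location: str = ""          # genomic-external / gap-internal / cassette-internal


@dataclass
class Assay:
    name: str
    fwd: Primer
    rev: Primer
    max_len: int = LR_PCR_MAX_LEN
    expected: dict = field(default_factory=dict)   # state -> list of sizes
    #: targeting-detection assays need an externally located primer; the
    #: cis/trans junction assay is deliberately all-vector-internal
    external_rule: bool = True


GF3 = Primer("gf3", "+", "genomic-external")
EX5 = Primer("ex5", "+", "gap-internal")
LAR_3 = Primer("LAR_3", "-", "cassette-internal")
HYGRO_1R = Primer("hygro_1R", "-", "cassette-internal")
LR = Primer("LR", "-", "cassette-internal")
R1_AMP_F2 = Primer("R1_amp_F2", "+", "cassette-internal")


def in_silico_pcr(template: AnnotatedSequence, fwd: Primer, rev: Primer,
                  max_len: int = LR_PCR_MAX_LEN) -> list[dict]:
    """All products of one primer pair on one template.

    One product per convergent site pair (forward site strictly upstream of
    the reverse site) with span at or below ``max_len``; reported in
    ascending size.  An empty list is "no band".
    """
    f_sites = [f for f in template.find(kind="primer_site", label=fwd.name)
               if f.strand == "+"]
    r_sites = [f for f in template.find(kind="primer_site", label=rev.name)
               if f.strand == "-"]
    products = []
    for fs, rs in itertools.product(f_sites, r_sites):
        if rs.end <= fs.start:
            continue
        size = rs.end - fs.start
        if size <= max_len:
            products.append({"size": size, "interval": (fs.start, rs.end)})
    return sorted(products, key=lambda p: p["size"])


def _external_ok(assay: Assay, gene: GeneModel) -> bool:
    """The screening rule: at least one primer must bind outside the vector
    homology region or inside the gap region."""
    return any(p.location in ("genomic-external", "gap-internal")
               for p in (assay.fwd, assay.rev))


def design_panel(gene: GeneModel, alleles: dict[str, AlleleMap],
                 vector: AnnotatedSequence | None = None) -> list[Assay]:
    """The four canonical assays with expected size classes computed from
    reference alleles (``alleles``: state -> AlleleMap)."""
    assays = [
        Assay("gf3+LAR_3", GF3, LAR_3),
        Assay("ex5+hygro_1R", EX5, HYGRO_1R),
        Assay("gf3+LR", GF3, LR),
        Assay("R1_amp_F2+hygro_1R", R1_AMP_F2, HYGRO_1R, external_rule=False),
    ]
    for assay in assays:
        if assay.external_rule and not _external_ok(assay, gene):
            raise DesignError(f"{assay.name}: no externally located primer")
        for state, allele in alleles.items():
            bands = in_silico_pcr(allele.seq, assay.fwd, assay.rev, assay.max_len)
            assay.expected[state] = [b["size"] for b in bands]
    for assay in assays:
        distinct = {tuple(v) for v in assay.expected.values()}
        if len(distinct) < 2 and assay.external_rule:
            logger.warning("%s does not discriminate any state pair", assay.name)
    return assays


def simulate_bands(cells: CellLine, panel: list[Assay]) -> dict[str, list[int]]:
    """Band pattern of a cell line: union of products over both alleles."""
    pattern: dict[str, list[int]] = {}
    for assay in panel:
        sizes = []
        for allele in cells.alleles():
            sizes += [p["size"] for p in
                      in_silico_pcr(allele.seq, assay.fwd, assay.rev, assay.max_len)]
        pattern[assay.name] = sorted(sizes)
    return pattern


def _sizes_match(observed: list, expected: list,
                 tol: float = SIZE_TOLERANCE) -> bool:
    if len(observed) != len(expected):
        return False
    for o, e in zip(sorted(observed), sorted(expected)):
        if e == 0 or abs(o - e) > tol * e:
            return False
    return True


#: states the screening workflow actually produces and calls.  tm1b
#: (Cre on tm1a, trap retained) is a valid transition but never a
#: screening intermediate here, and the long-range assays cannot separate
#: it from tm1a at the band-size tolerance, so it is not a call candidate.
WORKFLOW_STATES = ("wt", "tm1a", "tm1c", "tm1d", "tm2")

#: unordered allele-state pairs reachable by the engineering routes
REACHABLE_PAIRS = sorted({
    tuple(sorted(p)) for p in itertools.product(WORKFLOW_STATES, repeat=2)
    if sum(s in ("tm1a", "tm1c", "tm1d") for s in p) <= 1
    and p.count("tm2") <= 1
    and p != ("wt", "wt")})  # screened clones carry >=1 engineered allele;
                             # an all-absent pattern is a failed assay, not +/+


def call_genotype(pattern: dict, panel: list[Assay]) -> dict:
    """Unique allele-pair state consistent with the observed/absent bands.

    Candidate pairs are the reachable states; per pair and assay the
    expected bands are the union over the two allele states; matching uses
    the configured size tolerance.  More than one consistent pair ->
    ambiguous; none -> conflicts listed.
    """
    by_name = {a.name: a for a in panel}
    unknown = set(pattern) - set(by_name)
    if unknown:
        raise DataError(f"band pattern for unknown assay(s): {sorted(unknown)}")
    fits = []
    for pair in REACHABLE_PAIRS:
        ok = True
        for name, observed in pattern.items():
            assay = by_name[name]
            expected = sorted(assay.expected.get(pair[0], []) +
                              assay.expected.get(pair[1], []))
            if not _sizes_match(list(observed), expected):
                ok = False
                break
        if ok:
            fits.append(pair)

    def render(pair):
        a, b = pair
        sym = lambda s: "+" if s == "wt" else s
        # mutant-first rendering, matching the community shorthand
        ordered = sorted(pair, key=lambda s: (s == "wt", s))
        return f"{sym(ordered[0])}/{sym(ordered[1])}"

    if len(fits) == 1:
        return {"genotype": render(fits[0]), "confidence": "unique", "conflicts": []}
    if len(fits) > 1:
        return {"genotype": None, "confidence": "ambiguous",
                "candidates": [render(p) for p in fits], "conflicts": []}
    return {"genotype": None, "confidence": "none",
            "conflicts": [f"{n}: observed {pattern[n]}" for n in sorted(pattern)]}


# -- cis/trans and X-gal ---------------------------------------------------

def _has_r1(allele: AlleleMap) -> bool:
    return bool(allele.seq.find(kind="primer_site", label="R1_amp_F2"))


def _has_hyg(allele: AlleleMap) -> bool:
    return bool(allele.seq.find(kind="cassette", marker="hygro-GFP"))


def cis_trans_test(cells: CellLine, max_len: int = 10_000) -> str:
    """Junction PCR (R1_amp_F2 + hygro_1R) on each allele separately.

    ``cis``: a product on a single allele (both vector structures on the
    same chromosome).  ``trans``: no product on either allele, but the
    knockout-first-derived and insertion-trap structures are present across
    the two.  Anything else: ``not_applicable``.
    """
    per_allele = [in_silico_pcr(a.seq, R1_AMP_F2, HYGRO_1R, max_len)
                  for a in cells.alleles()]
    if any(per_allele):
        return "cis"
    has_r1 = any(_has_r1(a) for a in cells.alleles())
    has_hyg = any(_has_hyg(a) for a in cells.alleles())
    if has_r1 and has_hyg and not any(per_allele):
        return "trans"
    return "not_applicable"


def xgal_screen(cells: CellLine, gene: GeneModel,
                threshold: float = 1.0) -> dict:
    """Blue/white staining call: blue iff some allele expresses lacZ.

    A low-expression caveat is flagged when the locus sits below the
    targeted-trapping expression threshold — the stain may simply not be
    sensitive enough there.
    """
    blue = any("lacZ" in expression_outcome(a, gene, threshold)["markers_expressed"]
               for a in cells.alleles())
    low = gene.expression_pct_trfr < threshold
    return {"stain": "blue" if blue else "white", "low_expression_caveat": low}


# -- screening summaries ---------------------------------------------------

def load_reference_tallies() -> pd.DataFrame:
    """The published pI_hygGFP screening tallies (WT and tm1a/+ ES lines),
    shipped with the package as the reference input for summary reports."""
    from importlib.resources import files

    path = files("trapforge").joinpath("data/pI_hygGFP_targeting_tallies.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")



def _row_percent(row) -> float:
    if pd.notna(row.get("colonies_positive")):
        n, k = row["colonies_screened"], row["colonies_positive"]
        if k < 0 or k > n:
            raise DataError(f"{row['gene']}: positives {k} inconsistent with "
                            f"screened {n}")
        return round(100.0 * k / n, 1) if n else float("nan")
    return float(row["percent_targeted"])


def summarize_screen(table: pd.DataFrame) -> dict:
    """Targeting-frequency report from a screening tally table.

    Columns: ``gene``, ``line_genotype``, ``colonies_screened`` and either
    ``colonies_positive`` or ``percent_targeted``.  Rows are classed as
    wild-type controls or heterozygous (tm1a/+) experiments by genotype;
    duplicate lines of one gene are averaged before gene-level summaries.
    Gene-recovery counts (with/without bi-allelic clones) are taken over the
    heterozygous experimental rows.
    """
    if table.empty:
        logger.warning("empty screening table")
        return {"rows": table, "per_gene": {}, "summary": {}, "empty": True}
    t = table.copy()
    for col in ("colonies_screened",):
        if (t[col] < 0).any():
            raise DataError("negative colony counts")
    if "colonies_positive" not in t.columns:
        t["colonies_positive"] = np.nan
    if "percent_targeted" not in t.columns:
        t["percent_targeted"] = np.nan
    t["percent"] = t.apply(_row_percent, axis=1)
    t["line_class"] = np.where(
        t["line_genotype"].astype(str).str.contains("tm1a"), "tm1a/+", "wt")

    per_gene = (t.groupby(["line_class", "gene"])["percent"]
                 .mean().round(1))
    summary = {}
    for cls, vals in per_gene.groupby(level="line_class"):
        v = vals.droplevel("line_class")
        summary[cls] = {
            "n_genes": int(v.size),
            "mean_pct": round(float(v.mean()), 1),
            "min_pct": round(float(v.min()), 1),
            "max_pct": round(float(v.max()), 1),
            "per_gene": {g: float(x) for g, x in v.items()},
        }
    het = t[t["line_class"] == "tm1a/+"]
    if len(het):
        pos_by_gene = het.groupby("gene")["percent"].max()
        summary["genes_with_clones"] = sorted(pos_by_gene[pos_by_gene > 0].index)
        summary["genes_without_clones"] = sorted(pos_by_gene[pos_by_gene == 0].index)
    return {"rows": t, "per_gene": per_gene, "summary": summary}
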