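"""Bundled reference tables for a three-family early-onset atopic dermatitis
exome study design.

These small tables are the worked-example inputs the package documents
itself against: per-family candidate variant lists (with functional scores
and population frequencies), per-stage filter survivor counts, genotype
counts for a 112-case / 61-control validation cohort of three COL6A6 SNPs,
and the linkage-locus map used for proximity annotation.

Two rows are printed inconsistently in the source material and are kept in
both forms: the EDN1 PhastCons value for family A conflicts with the value
printed for the same site (rs5370) in family B, so
:func:`family_variants` exposes a ``harmonized`` switch that substitutes the
cross-table value.  Inconsistencies are in the data, not silently edited.
"""

from __future__ import annotations

from .assoc import CaseControlCounts
from .filters import STAGES, FilterTrace
from .discovery import GeneCall
from .variants import AnnotatedVariant, Effect, Impact, LinkageLocus

__all__ = [
    "FAMILIES",
    "family_variant_rows",
    "family_variants",
    "family_gene_calls",
    "reference_trace",
    "linkage_loci",
    "linkage_gene_positions",
    "case_control_counts",
]

FAMILIES = ("A", "B", "C")

# Per-family candidate variant rows.  Columns:
# (gene, rsid, chrom, pos, aa_change, effect, sift, polyphen2_hdiv, phylop,
#  phastcons, af_global, af_east_asian, af_korean, tier)
# None encodes a missing (".") annotation.
_N = None
_ROWS: dict[str, list[tuple]] = {
    "A": [
        ("COL6A6", "rs16830494", "chr3", 130_361_856, "R1739Q", "NON_SYNONYMOUS_CODING",
         0.04, 0.272, 1.703, 0.995, 0.12, 0.19, 0.188, "common"),
        ("ANKRD35", "rs11579366", "chr1", 145_562_293, "E661Q", "NON_SYNONYMOUS_CODING",
         0.38, 0.971, 5.285, 1.0, 0.39, 0.26, 0.233, "common"),
        ("TUFT1", "rs3828054", "chr1", 151_512_895, "Q18R", "NON_SYNONYMOUS_CODING",
         0.77, 0.688, 1.688, 0.288, 0.1, 0.03, 0.047, "common"),
        ("TMEM175", "rs34311866", "chr4", 951_947, "M393T", "NON_SYNONYMOUS_CODING",
         0.01, 0.0, 1.299, 0.999, 0.12, 0.12, 0.155, "common"),
        ("EDN1", "rs5370", "chr6", 12_296_255, "K198N", "NON_SYNONYMOUS_CODING",
         0.08, 0.454, 0.049, 0.001, 0.21, 0.28, 0.258, "common"),
        ("NRAP", "rs2270182", "chr10", 115_392_919, "N519I", "NON_SYNONYMOUS_CODING",
         0.19, 0.958, 2.477, 1.0, 0.26, 0.20, 0.205, "common"),
        ("HGFAC", "rs16844401", "chr4", 3_449_652, "R509H", "NON_SYNONYMOUS_CODING",
         0.22, 0.943, 2.662, 0.593, 0.07, 0.10, 0.115, "common"),
        ("UNC93A", "rs2235197", "chr6", 167_709_702, "W151*", "STOP_GAINED",
         _N, _N, 4.525, 1.0, 0.1, 0.15, 0.163, "common"),
        ("ABCA13", "rs1771229", "chr7", 48_313_881, "F1540L", "NON_SYNONYMOUS_CODING",
         _N, 0.997, 2.325, 0.614, 0.11, 0.17, 0.255, "common"),
        ("SSPO", "rs1005603", "chr7", 149_516_881, "S4028I", "NON_SYNONYMOUS_CODING",
         _N, _N, _N, _N, 0.2, 0.19, 0.181, "common"),
        ("TTC40", "rs12781609", "chr10", 134_748_331, "S264N", "NON_SYNONYMOUS_CODING",
         _N, _N, _N, _N, 0.37, 0.36, 0.412, "common"),
        ("DNAH17", None, "chr17", 76_567_792, "I204M", "NON_SYNONYMOUS_CODING",
         0.11, _N, 1.926, 0.992, _N, _N, _N, "rare"),
        ("COL6A6", "rs200963433", "chr3", 130_289_976, "R906C", "NON_SYNONYMOUS_CODING",
         0.0, 1.0, 4.596, 1.0, 0.0014, 0.01, 0.017, "rare"),
    ],
    "B": [
        ("COL6A6", "rs59021909", "chr3", 130_285_929, "P556S", "NON_SYNONYMOUS_CODING",
         0.11, 0.999, 2.136, 0.997, 0.09, 0.08, 0.119, "common"),
        ("UVSSA", "rs2276904", "chr4", 1_349_029, "R391H", "NON_SYNONYMOUS_CODING",
         _N, _N, _N, _N, 0.23, 0.42, 0.374, "common"),
        ("TUFT1", "rs3828054", "chr1", 151_512_895, "Q18R", "NON_SYNONYMOUS_CODING",
         0.77, 0.688, 1.688, 0.763, 0.1, 0.03, 0.047, "common"),
        ("TMEM175", "rs34311866", "chr4", 951_947, "M393T", "NON_SYNONYMOUS_CODING",
         0.01, 0.0, 1.299, 0.563, 0.12, 0.12, 0.155, "common"),
        ("EDN1", "rs5370", "chr6", 12_296_255, "K198N", "NON_SYNONYMOUS_CODING",
         0.08, 0.454, 0.049, 0.895, 0.21, 0.28, 0.258, "common"),
        ("NRAP", "rs868738", "chr10", 115_381_747, "R884C", "NON_SYNONYMOUS_CODING",
         0.01, 0.986, 4.833, 1.0, 0.24, 0.17, 0.198, "common"),
        ("CDX1", "rs370852694", "chr5", 149_546_819, "A127E", "NON_SYNONYMOUS_CODING",
         0.87, 0.458, 1.235, 0.996, _N, _N, 0.027, "rare"),
        ("DNAH17", "rs78098467", "chr17", 76_510_974, "A1332V", "NON_SYNONYMOUS_CODING",
         0.6, _N, 4.052, 1.0, 0.01, 0.04, 0.037, "rare"),
        ("ANKRD35", "rs146839643", "chr1", 145_560_094, "C194R", "NON_SYNONYMOUS_CODING",
         0.01, 1.0, 3.419, 1.0, 0.0037, 0.01, 0.016, "rare"),
    ],
    "C": [
        ("UVSSA", "rs2276904", "chr4", 1_349_029, "R391H", "NON_SYNONYMOUS_CODING",
         _N, _N, _N, _N, 0.23, 0.42, 0.374, "common"),
        ("HGFAC", "rs3748034", "chr4", 3_446_091, "A218S", "NON_SYNONYMOUS_CODING",
         0.38, 0.659, 2.0, 1.0, 0.15, 0.28, 0.305, "common"),
        ("UNC93A", "rs2235197", "chr6", 167_709_702, "W151*", "STOP_GAINED",
         _N, _N, 4.525, 1.0, 0.1, 0.15, 0.163, "common"),
        ("ABCA13", "rs17712299", "chr7", 48_313_881, "F1540L", "NON_SYNONYMOUS_CODING",
         _N, 0.997, 2.325, 0.85, 0.11, 0.17, 0.255, "common"),
        ("SSPO", "rs1005603", "chr7", 149_516_881, "S4028I", "NON_SYNONYMOUS_CODING",
         _N, _N, _N, 1.0, 0.2, 0.19, 0.181, "common"),
        ("TTC40", None, "chr10", 134_679_632, "T1596M", "NON_SYNONYMOUS_CODING",
         _N, _N, _N, _N, _N, _N, _N, "common"),
        ("COL6A6", "rs200963433", "chr3", 130_289_976, "R906C", "NON_SYNONYMOUS_CODING",
         0.0, 1.0, 4.596, 1.0, 0.0014, 0.01, 0.017, "rare"),
        ("CDX1", "rs370852694", "chr5", 149_546_819, "A127E", "NON_SYNONYMOUS_CODING",
         0.87, 0.458, 1.235, 0.996, _N, _N, 0.027, "rare"),
    ],
}

# The family-A EDN1 PhastCons entry conflicts with the family-B entry for the
# identical site; the harmonized view substitutes the cross-table value.
_HARMONIZED = {("A", "EDN1"): {"phastcons": 0.895}}

_FIELDS = (
    "gene", "rsid", "chrom", "pos", "aa_change", "effect", "sift",
    "polyphen2_hdiv", "phylop", "phastcons", "af_global", "af_east_asian",
    "af_korean", "tier",
)


def family_variant_rows(family: str, harmonized: bool = False) -> list[dict]:
    """The candidate variant rows of one family as dicts (as printed, or with
    cross-table-inconsistent cells harmonized)."""
    rows = []
    for raw in _ROWS[family]:
        row = dict(zip(_FIELDS, raw))
        if harmonized:
            row.update(_HARMONIZED.get((family, row["gene"]), {}))
        rows.append(row)
    return rows


def family_variants(
    family: str, harmonized: bool = False
) -> list[tuple[AnnotatedVariant, str]]:
    """(AnnotatedVariant, tier) pairs for one family's candidate list.

    Alleles are placeholders (the tables print amino-acid changes, not
    nucleotides); variant identity still distinguishes every row by position.
    """
    out = []
    for row in family_variant_rows(family, harmonized=harmonized):
        tier = row.pop("tier")
        effect = Effect.parse(row.pop("effect"))
        impact = Impact.HIGH if effect is Effect.STOP_GAINED else Impact.MODERATE
        var = AnnotatedVariant(ref="N", alt="A", effect=effect, impact=impact, **row)
        out.append((var, tier))
    return out


def family_gene_calls() -> dict[str, list[GeneCall]]:
    """Per-family GeneCall lists (gene, position, rare flag) for discovery."""
    calls: dict[str, list[GeneCall]] = {}
    for family in FAMILIES:
        calls[family] = [
            GeneCall(
                gene=row["gene"],
                chrom=row["chrom"],
                pos=row["pos"],
                rare=row["tier"] == "rare",
            )
            for row in family_variant_rows(family)
        ]
    return calls


#: Per-family survivor counts after each cascade stage (dominant model).
_TRACE_COUNTS: dict[str, tuple[int, ...]] = {
    # raw, effect, impact, deleteriousness, phylop, phastcons, af_global, af_korean
    "A": (75_233, 2_799, 502, 278, 234, 200, 33, 31),
    "B": (5_643, 2_489, 516, 258, 225, 173, 60, 54),
    "C": (3_227, 2_198, 443, 231, 206, 156, 53, 49),
}


def reference_trace() -> FilterTrace:
    """The study's per-family filter survivor counts as a FilterTrace."""
    return FilterTrace(
        {fam: dict(zip(STAGES, counts)) for fam, counts in _TRACE_COUNTS.items()}
    )


def linkage_loci() -> list[LinkageLocus]:
    """Linkage loci previously associated with atopic dermatitis."""
    return [
        LinkageLocus("3q21", "chr3", 122_200_000, 129_500_000),
        LinkageLocus("5q31-33", "chr5", 131_200_000, 160_500_000),
        LinkageLocus("1q21", "chr1", 143_200_000, 155_100_000),
    ]


def linkage_gene_positions() -> dict[str, tuple[str, int]]:
    """Representative positions of the five genes assessed against the
    linkage-locus map.  Exact coordinates are used where the candidate tables
    print them; FLG (reported only to Mb precision) uses the Mb value."""
    return {
        "COL6A6": ("chr3", 130_285_929),
        "CDX1": ("chr5", 149_546_819),
        "ANKRD35": ("chr1", 145_560_094),
        "TUFT1": ("chr1", 151_512_895),
        "FLG": ("chr1", 152_200_000),
    }


def case_control_counts() -> list[CaseControlCounts]:
    """Genotype counts for the three COL6A6 SNPs in 112 cases / 61 controls."""
    return [
        CaseControlCounts(
            snp="rs16830494", ref_allele="G", alt_allele="A",
            control=(39, 21, 1), case=(79, 29, 3),
        ),
        CaseControlCounts(
            snp="rs59021909", ref_allele="C", alt_allele="T",
            control=(47, 14, 0), case=(89, 21, 2),
        ),
        CaseControlCounts(
            snp="rs200963433", ref_allele="C", alt_allele="T",
            control=(60, 1, 0), case=(108, 4, 0),
        ),
    ]
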