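"""Per-family co-segregation of variants with affection status.

The discovery design is a fully penetrant autosomal-dominant model on small
nuclear families: a variant co-segregates when every affected member is
heterozygous and every unaffected member is homozygous for the reference
allele.  Any missing genotype fails segregation (strict, specificity-first).

A recessive mode is provided for reuse (affected members homozygous for the
alternate allele, unaffected members anything but) although discovery runs
use the dominant model.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .variants import Genotype, GenotypeMatrix, Pedigree, VariantKey

__all__ = [
    "dominant_segregation",
    "recessive_segregation",
    "apply_segregation",
]


def dominant_segregation(
    key: VariantKey,
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    family: str,
    allow_hom_alt: bool = False,
) -> bool:
    """True iff the variant fits the dominant pattern in one family.

    Affected samples must be heterozygous (strict: a homozygous-alternate
    affected sample fails unless ``allow_hom_alt``); unaffected samples must
    be homozygous reference; any MISSING call fails.

    Raises
    ------
    KeyError
        If the family id is unknown to the pedigree.
    """
    affected = ped.affected(family)  # raises KeyError for unknown family
    unaffected = ped.unaffected(family)
    ok_affected = (
        {Genotype.HET, Genotype.HOM_ALT} if allow_hom_alt else {Genotype.HET}
    )
    for sample in affected:
        if genotypes.call(key, sample) not in ok_affected:
            return False
    for sample in unaffected:
        if genotypes.call(key, sample) != Genotype.HOM_REF:
            return False
    return True


def recessive_segregation(
    key: VariantKey,
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    family: str,
) -> bool:
    """True iff affected samples are HOM_ALT and unaffected samples are
    carriers or HOM_REF (never HOM_ALT); MISSING fails."""
    for sample in ped.affected(family):
        if genotypes.call(key, sample) != Genotype.HOM_ALT:
            return False
    for sample in ped.unaffected(family):
        if genotypes.call(key, sample) not in (Genotype.HOM_REF, Genotype.HET):
            return False
    return True


def apply_segregation(
    keys: Iterable[VariantKey],
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    model: str = "dominant",
    allow_hom_alt: bool = False,
) -> dict[str, set[VariantKey]]:
    """Per-family sets of co-segregating variants; families are independent.

    Variants absent from the genotype matrix are skipped (they cannot be
    evaluated, and strict missingness would fail them anyway).
    """
    if model not in ("dominant", "recessive"):
        raise ValueError(f"unknown inheritance model {model!r}")
    result: dict[str, set[VariantKey]] = {fam: set() for fam in ped.families}
    for key in keys:
        if not genotypes.has_variant(key):
            continue
        for family in ped.families:
            if model == "dominant":
                ok = dominant_segregation(
                    key, genotypes, ped, family, allow_hom_alt=allow_hom_alt
                )
            else:
                ok = recessive_segregation(key, genotypes, ped, family)
            if ok:
                result[family].add(key)
    return result
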