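"""Core domain types: annotated variants, genotype matrices, pedigrees, loci.

The pipeline works on already-called, already-annotated exome variants.  Each
variant carries a functional-consequence category (the snpEff "classic" effect
vocabulary), an impact class, deleteriousness predictions (SIFT,
PolyPhen2-HDIV), conservation scores (PhyloP, PhastCons) and population allele
frequencies (global, East-Asian, Korean reference panel).  Any annotation may
be missing; missingness is represented as ``None`` and is semantically
distinct from 0.0 (a SIFT of 0.0 is maximally damaging, not absent).

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import VocabularyError

__all__ = [
    "Effect",
    "Impact",
    "Genotype",
    "AnnotatedVariant",
    "VariantKey",
    "GenotypeMatrix",
    "PedMember",
    "Pedigree",
    "LinkageLocus",
    "CHROMOSOMES",
    "normalize_chrom",
]

#: Closed chromosome vocabulary (human autosomes + sex chromosomes + MT).
CHROMOSOMES: tuple[str, ...] = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrMT"]
)

_CHROM_ALIASES = {c.removeprefix("chr"): c for c in CHROMOSOMES}
_CHROM_ALIASES.update({c: c for c in CHROMOSOMES})
_CHROM_ALIASES["chrM"] = "chrMT"
_CHROM_ALIASES["M"] = "chrMT"


def normalize_chrom(token: str) -> str:
    """Normalize a chromosome token ('3', 'chr3') to the canonical 'chr3'.

    Raises
    ------
    VocabularyError
        If the token is not a recognized human chromosome.
    """
    tok = token.strip()
    if tok in _CHROM_ALIASES:
        return _CHROM_ALIASES[tok]
    raise VocabularyError(f"unknown chromosome {token!r}")


class Effect(str, Enum):
    """Functional-consequence categories (snpEff classic effect names)."""

    NON_SYNONYMOUS_CODING = "NON_SYNONYMOUS_CODING"
    SYNONYMOUS_CODING = "SYNONYMOUS_CODING"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    START_LOST = "START_LOST"
    START_GAINED = "START_GAINED"
    SPLICE_SITE_ACCEPTOR = "SPLICE_SITE_ACCEPTOR"
    SPLICE_SITE_DONOR = "SPLICE_SITE_DONOR"
    FRAME_SHIFT = "FRAME_SHIFT"
    CODON_CHANGE = "CODON_CHANGE"
    CODON_INSERTION = "CODON_INSERTION"
    CODON_DELETION = "CODON_DELETION"
    CODON_CHANGE_PLUS_CODON_INSERTION = "CODON_CHANGE_PLUS_CODON_INSERTION"
    CODON_CHANGE_PLUS_CODON_DELETION = "CODON_CHANGE_PLUS_CODON_DELETION"
    UTR_5_PRIME = "UTR_5_PRIME"
    UTR_3_PRIME = "UTR_3_PRIME"
    INTRON = "INTRON"
    INTERGENIC = "INTERGENIC"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    NON_CODING_EXON = "NON_CODING_EXON"

    @classmethod
    def parse(cls, token: str) -> "Effect":
        """Parse an effect token, tolerating case/space/hyphen variation.

        'non-synonymous coding' and 'NON_SYNONYMOUS_CODING' both parse; an
        unrecognized token raises :class:`VocabularyError` instead of being
        silently coerced.
        """
        norm = re.sub(r"[\s\-]+", "_", token.strip()).upper()
        try:
            return cls(norm)
        except ValueError:
            raise VocabularyError(f"unknown variant effect {token!r}") from None


class Impact(str, Enum):
    """snpEff impact classes."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"

    @classmethod
    def parse(cls, token: str) -> "Impact":
        try:
            return cls(token.strip().upper())
        except ValueError:
            raise VocabularyError(f"unknown impact class {token!r}") from None


class Genotype(IntEnum):
    """Diploid genotype call states."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


#: A variant's identity: (chrom, pos, ref, alt).
VariantKey = tuple[str, int, str, str]

_SCORE_RANGES = {
    "sift": (0.0, 1.0),
    "polyphen2_hdiv": (0.0, 1.0),
    "phastcons": (0.0, 1.0),
    "af_global": (0.0, 1.0),
    "af_east_asian": (0.0, 1.0),
    "af_korean": (0.0, 1.0),
}


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant (one ALT allele) with its annotations.

    ``rsid`` is treated as an opaque label and never used for identity:
    identity is the ``key`` tuple (chrom, pos, ref, alt).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: Effect
    impact: Impact
    rsid: str | None = None
    aa_change: str | None = None
    sift: float | None = None
    polyphen2_hdiv: float | None = None
    phylop: float | None = None
    phastcons: float | None = None
    af_global: float | None = None
    af_east_asian: float | None = None
    af_korean: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref!r})")
        if not isinstance(self.effect, Effect):
            object.__setattr__(self, "effect", Effect.parse(str(self.effect)))
        if not isinstance(self.impact, Impact):
            object.__setattr__(self, "impact", Impact.parse(str(self.impact)))
        for name, (lo, hi) in _SCORE_RANGES.items():
            val = getattr(self, name)
            if val is not None and not (lo <= val <= hi):
                raise ValueError(
                    f"{name}={val} outside legal range [{lo}, {hi}] "
                    f"for variant {self.chrom}:{self.pos}"
                )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


class GenotypeMatrix:
    """Genotype calls for a set of variants x a set of samples.

    Stored as an int8 matrix coded with :class:`Genotype` values; every
    (variant, sample) pair has exactly one call (MISSING is a call).
    """

    def __init__(
        self,
        variant_keys: Sequence[VariantKey],
        samples: Sequence[str],
        calls: np.ndarray | None = None,
    ):
        self.variant_keys: list[VariantKey] = list(variant_keys)
        self.samples: list[str] = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers in genotype matrix")
        if calls is None:
            calls = np.full(
                (len(self.variant_keys), len(self.samples)),
                Genotype.MISSING,
                dtype=np.int8,
            )
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.variant_keys), len(self.samples)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.variant_keys)} variants x {len(self.samples)} samples"
            )
        legal = np.isin(calls, [g.value for g in Genotype])
        if not legal.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.calls = calls
        self._vindex = {k: i for i, k in enumerate(self.variant_keys)}
        self._sindex = {s: j for j, s in enumerate(self.samples)}

    def call(self, key: VariantKey, sample: str) -> Genotype:
        return Genotype(int(self.calls[self._vindex[key], self._sindex[sample]]))

    def set_call(self, key: VariantKey, sample: str, g: Genotype) -> None:
        self.calls[self._vindex[key], self._sindex[sample]] = int(g)

    def has_variant(self, key: VariantKey) -> bool:
        return key in self._vindex

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variant_keys == other.variant_keys
            and self.samples == other.samples
            and bool(np.array_equal(self.calls, other.calls))
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_variants} variants x {self.n_samples} samples)"

    @staticmethod
    def merge(matrices: Iterable["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Union of several matrices (e.g. one per family).

        Variants are keyed by (chrom, pos, ref, alt); samples must be unique
        across inputs.  Pairs absent from every input matrix are MISSING.
        """
        matrices = list(matrices)
        keys: list[VariantKey] = []
        seen: set[VariantKey] = set()
        samples: list[str] = []
        for m in matrices:
            for k in m.variant_keys:
                if k not in seen:
                    seen.add(k)
                    keys.append(k)
            samples.extend(m.samples)
        merged = GenotypeMatrix(keys, samples)
        col = 0
        for m in matrices:
            rows = [merged._vindex[k] for k in m.variant_keys]
            merged.calls[np.asarray(rows, dtype=int)[:, None],
                         np.arange(col, col + m.n_samples)[None, :]] = m.calls
            col += m.n_samples
        return merged


@dataclass(frozen=True)
class PedMember:
    family: str
    individual: str
    father: str = "0"
    mother: str = "0"
    sex: int = 0  # 1=male, 2=female, 0=unknown
    affected: bool = False
    role: str = ""  # free-text label, e.g. "father", "child"


class Pedigree:
    """Family membership and affection status of the cohort samples."""

    def __init__(self, members: Iterable[PedMember]):
        self.members: list[PedMember] = list(members)
        ids = [m.individual for m in self.members]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample id(s) in pedigree: {dup}")
        self._by_family: dict[str, list[PedMember]] = {}
        for m in self.members:
            self._by_family.setdefault(m.family, []).append(m)

    @property
    def families(self) -> list[str]:
        return list(self._by_family)

    def family_members(self, family: str) -> list[PedMember]:
        if family not in self._by_family:
            raise KeyError(f"unknown family id {family!r}")
        return list(self._by_family[family])

    def affected(self, family: str) -> list[str]:
        return [m.individual for m in self.family_members(family) if m.affected]

    def unaffected(self, family: str) -> list[str]:
        return [m.individual for m in self.family_members(family) if not m.affected]

    def samples(self, family: str | None = None) -> list[str]:
        if family is None:
            return [m.individual for m in self.members]
        return [m.individual for m in self.family_members(family)]

    def validate(self) -> list[str]:
        """Return human-readable warnings (e.g. a family with no affected
        member); the standard study design has >=1 affected and >=1 unaffected
        per family."""
        warnings: list[str] = []
        for fam in self.families:
            if not self.affected(fam):
                warnings.append(f"family {fam!r} has no affected member")
            if not self.unaffected(fam):
                warnings.append(f"family {fam!r} has no unaffected member")
        return warnings

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:
        return f"Pedigree({len(self.members)} samples, {len(self.families)} families)"


@dataclass(frozen=True)
class LinkageLocus:
    """A chromosomal interval previously linked to the phenotype (e.g. the
    atopic-dermatitis susceptibility locus 3q21)."""

    name: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int  # 1-based inclusive

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"locus {self.name}: start {self.start_bp} > end {self.end_bp}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start_bp <= pos <= self.end_bp

    def distance_to(self, chrom: str, pos: int) -> int | None:
        """Base-pair distance from pos to the interval (0 if inside); None if
        on a different chromosome."""
        if normalize_chrom(chrom) != self.chrom:
            return None
        if pos < self.start_bp:
            return self.start_bp - pos
        if pos > self.end_bp:
            return pos - self.end_bp
        return 0
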