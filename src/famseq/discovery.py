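"""Cross-family candidate discovery: gene-level overlap and locus proximity.

After per-family prioritization, genes recurrently hit across families are
the candidates.  Overlap is at GENE level — different variants of the same
gene in different families count as a shared hit.  Candidates are then
annotated against previously reported linkage loci: a gene whose variant
falls inside a locus interval is WITHIN; within a configurable margin of an
interval end, PROXIMAL; otherwise NONE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .variants import LinkageLocus, normalize_chrom

__all__ = [
    "GeneCall",
    "CandidateGene",
    "LocusAnnotation",
    "overlapping_genes",
    "rare_overlap_genes",
    "locus_proximity",
    "gene_calls_from_cascade",
]


@dataclass(frozen=True)
class GeneCall:
    """One prioritized variant observation: a gene hit in one family."""

    gene: str
    chrom: str
    pos: int
    rare: bool  # True if the variant sits in the rare tier

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class CandidateGene:
    """A gene observed in the candidate lists of one or more families."""

    gene: str
    families_observed: frozenset[str]
    has_rare_variant: bool
    #: per family, the (chrom, pos) of the member variant(s), sorted.
    positions: Mapping[str, tuple[tuple[str, int], ...]]

    def __post_init__(self) -> None:
        if not self.families_observed:
            raise ValueError(f"gene {self.gene}: no observing families")
        chroms = {c for plist in self.positions.values() for c, _ in plist}
        if len(chroms) > 1:
            raise ValueError(
                f"gene {self.gene}: representative positions span several "
                f"chromosomes {sorted(chroms)}"
            )

    @property
    def chrom(self) -> str:
        return next(c for plist in self.positions.values() for c, _ in plist)

    @property
    def all_positions(self) -> list[tuple[str, int]]:
        return sorted({p for plist in self.positions.values() for p in plist})


def overlapping_genes(
    per_family_calls: Mapping[str, Iterable[GeneCall]],
    min_families: int = 2,
) -> dict[str, CandidateGene]:
    """Genes present in the candidate lists of at least ``min_families``
    families.

    ``min_families`` larger than the number of families simply yields an
    empty result.  The result is monotone decreasing in ``min_families``.
    """
    if min_families < 1:
        raise ValueError("min_families must be >= 1")
    observed: dict[str, dict[str, list[GeneCall]]] = {}
    for family, calls in per_family_calls.items():
        for call in calls:
            observed.setdefault(call.gene, {}).setdefault(family, []).append(call)
    out: dict[str, CandidateGene] = {}
    for gene, fam_calls in observed.items():
        if len(fam_calls) < min_families:
            continue
        out[gene] = CandidateGene(
            gene=gene,
            families_observed=frozenset(fam_calls),
            has_rare_variant=any(
                c.rare for calls in fam_calls.values() for c in calls
            ),
            positions={
                fam: tuple(sorted((c.chrom, c.pos) for c in calls))
                for fam, calls in fam_calls.items()
            },
        )
    return out


def rare_overlap_genes(
    candidates: Mapping[str, CandidateGene],
) -> dict[str, CandidateGene]:
    """The subset of overlap genes carrying a rare-tier variant in >=1 family."""
    return {g: c for g, c in candidates.items() if c.has_rare_variant}


@dataclass(frozen=True)
class LocusAnnotation:
    """Relationship of one candidate gene to the linkage-locus map."""

    status: str  # WITHIN | PROXIMAL | NONE
    locus: str | None
    distance_bp: int | None  # 0 when WITHIN; None when NONE


def locus_proximity(
    candidates: Mapping[str, CandidateGene],
    loci: Sequence[LinkageLocus],
    margin_bp: int = 1_000_000,
) -> dict[str, LocusAnnotation]:
    """Annotate each candidate gene against the linkage loci.

    WITHIN if any representative position falls inside a same-chromosome
    locus; PROXIMAL if the closest position is within ``margin_bp`` of an
    interval end; NONE otherwise.  Ties are broken by smallest distance.
    With ``margin_bp=0`` the PROXIMAL class is empty by construction.
    """
    if margin_bp < 0:
        raise ValueError("margin_bp must be >= 0")
    out: dict[str, LocusAnnotation] = {}
    for gene, cand in candidates.items():
        best: tuple[int, str] | None = None
        for chrom, pos in cand.all_positions:
            for locus in loci:
                dist = locus.distance_to(chrom, pos)
                if dist is None:
                    continue
                if best is None or dist < best[0]:
                    best = (dist, locus.name)
        if best is None:
            out[gene] = LocusAnnotation("NONE", None, None)
        elif best[0] == 0:
            out[gene] = LocusAnnotation("WITHIN", best[1], 0)
        elif best[0] <= margin_bp:
            out[gene] = LocusAnnotation("PROXIMAL", best[1], best[0])
        else:
            out[gene] = LocusAnnotation("NONE", None, None)
    return out


def gene_calls_from_cascade(variants, result) -> dict[str, list[GeneCall]]:
    """Build per-family GeneCall lists from a CascadeResult.

    Each family's list is the union of its common and rare tiers, with the
    rare flag set per variant.
    """
    by_key = {v.key: v for v in variants}
    calls: dict[str, list[GeneCall]] = {}
    for family in result.trace.families:
        fam_calls = []
        for tier, keys in (("common", result.common[family]), ("rare", result.rare[family])):
            for key in sorted(keys):
                v = by_key[key]
                fam_calls.append(
                    GeneCall(gene=v.gene, chrom=v.chrom, pos=v.pos, rare=tier == "rare")
                )
        calls[family] = fam_calls
    return calls
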