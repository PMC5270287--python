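"""The seven-stage annotation filter cascade with per-family accounting.

Variants that co-segregate with affection status (see :mod:`famseq.segregation`)
are pushed through seven successive annotation filters:

1. effect         — keep protein-altering consequence categories
2. impact         — keep HIGH / MODERATE impact classes
3. deleteriousness — SIFT / PolyPhen2-HDIV damage predictions
4. phylop         — positive PhyloP (conserved site)
5. phastcons      — PhastCons >= 0.2 (conserved element)
6. af_global      — global (1000 Genomes) frequency < 0.01 or unknown
7. af_korean      — Korean reference-panel MAF < 0.02 or unknown

Survivors of stages 1-5 form the candidate pool; those that also clear the
two frequency stages are the *rare* tier, the rest the *common* tier.  A
:class:`FilterTrace` records the per-family survivor count after every stage,
the accounting used to report per-family attrition.

Missing-score semantics: a missing annotation passes its filter by default
("unknown" is not evidence against a variant).  Stage 3 removes a variant
only when BOTH predictions are present and BOTH are benign — the only rule
consistent with keeping variants that carry a tolerated SIFT alongside an
absent PolyPhen call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError
from .segregation import apply_segregation
from .variants import (
    AnnotatedVariant,
    Effect,
    GenotypeMatrix,
    Impact,
    Pedigree,
    VariantKey,
)

__all__ = [
    "STAGES",
    "FILTER_STAGES",
    "FilterConfig",
    "FilterTrace",
    "CascadeResult",
    "effect_filter",
    "impact_filter",
    "deleteriousness_filter",
    "phylop_filter",
    "phastcons_filter",
    "global_frequency_filter",
    "korean_frequency_filter",
    "variant_passes_stage",
    "run_cascade",
    "cascade_presegregated",
    "summarize_trace",
]

#: Trace stages in order; "raw" is the post-segregation input count.
STAGES: tuple[str, ...] = (
    "raw",
    "effect",
    "impact",
    "deleteriousness",
    "phylop",
    "phastcons",
    "af_global",
    "af_korean",
)

#: The seven filter stages (excludes the "raw" bookkeeping stage).
FILTER_STAGES: tuple[str, ...] = STAGES[1:]

#: Effect categories kept by stage 1: the protein-altering consequences.
DEFAULT_EFFECT_KEEP: frozenset[Effect] = frozenset(
    {
        Effect.NON_SYNONYMOUS_CODING,
        Effect.STOP_GAINED,
        Effect.STOP_LOST,
        Effect.START_LOST,
        Effect.SPLICE_SITE_ACCEPTOR,
        Effect.SPLICE_SITE_DONOR,
        Effect.FRAME_SHIFT,
        Effect.CODON_CHANGE,
        Effect.CODON_INSERTION,
        Effect.CODON_DELETION,
        Effect.CODON_CHANGE_PLUS_CODON_INSERTION,
        Effect.CODON_CHANGE_PLUS_CODON_DELETION,
    }
)

DEFAULT_IMPACT_KEEP: frozenset[Impact] = frozenset({Impact.HIGH, Impact.MODERATE})

#: Stages whose predicate can encounter a missing annotation.
_MISSING_STAGES = ("deleteriousness", "phylop", "phastcons", "af_global", "af_korean")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and keep-sets for the seven-stage cascade.

    Boundary semantics (field by field):

    - ``sift_damaging_max``: SIFT strictly below this is damaging (0.05 itself
      is tolerated).
    - ``polyphen_damaging_min``: PolyPhen2-HDIV at or above this is at least
      "possibly damaging" (0.453 itself qualifies).
    - ``phylop_min``: strictly greater passes (exactly 0 fails).
    - ``phastcons_min``: at or above passes (exactly 0.2 passes).
    - ``af_global_max`` / ``af_korean_max``: strictly below passes (a
      frequency exactly at the maximum fails).

    ``missing_passes`` controls, per score-bearing stage, whether a missing
    annotation passes that stage (default: yes for every stage).
    """

    effect_keep: frozenset[Effect] = DEFAULT_EFFECT_KEEP
    impact_keep: frozenset[Impact] = DEFAULT_IMPACT_KEEP
    sift_damaging_max: float = 0.05
    polyphen_damaging_min: float = 0.453
    phylop_min: float = 0.0
    phastcons_min: float = 0.2
    af_global_max: float = 0.01
    af_korean_max: float = 0.02
    missing_passes: Mapping[str, bool] = field(
        default_factory=lambda: {s: True for s in _MISSING_STAGES}
    )

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("sift_damaging_max", 0.0, 1.0),
            ("polyphen_damaging_min", 0.0, 1.0),
            ("phastcons_min", 0.0, 1.0),
            ("af_global_max", 0.0, 1.0),
            ("af_korean_max", 0.0, 1.0),
        ):
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise ConfigError(f"{name}={val} outside legal range [{lo}, {hi}]")
        mp = {s: True for s in _MISSING_STAGES}
        unknown = set(self.missing_passes) - set(mp)
        if unknown:
            raise ConfigError(f"missing_passes has unknown stage(s) {sorted(unknown)}")
        mp.update(self.missing_passes)
        object.__setattr__(self, "missing_passes", mp)
        object.__setattr__(
            self, "effect_keep", frozenset(Effect(e) for e in self.effect_keep)
        )
        object.__setattr__(
            self, "impact_keep", frozenset(Impact(i) for i in self.impact_keep)
        )

    # -- (de)serialization: the threshold set is echoed in every report ------

    def to_dict(self) -> dict:
        return {
            "effect_keep": sorted(e.value for e in self.effect_keep),
            "impact_keep": sorted(i.value for i in self.impact_keep),
            "sift_damaging_max": self.sift_damaging_max,
            "polyphen_damaging_min": self.polyphen_damaging_min,
            "phylop_min": self.phylop_min,
            "phastcons_min": self.phastcons_min,
            "af_global_max": self.af_global_max,
            "af_korean_max": self.af_korean_max,
            "missing_passes": dict(self.missing_passes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        kwargs = dict(d)
        if "effect_keep" in kwargs:
            kwargs["effect_keep"] = frozenset(
                Effect.parse(e) for e in kwargs["effect_keep"]
            )
        if "impact_keep" in kwargs:
            kwargs["impact_keep"] = frozenset(
                Impact.parse(i) for i in kwargs["impact_keep"]
            )
        return cls(**kwargs)


# -- the seven per-variant predicates ----------------------------------------


def effect_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Stage 1: keep protein-altering consequence categories."""
    return v.effect in cfg.effect_keep


def impact_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Stage 2: keep HIGH/MODERATE impact variants."""
    return v.impact in cfg.impact_keep


def deleteriousness_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Stage 3: SIFT / PolyPhen2 damage predictions.

    A variant is removed only when both scores are present and both are
    benign (SIFT tolerated AND PolyPhen below "possibly damaging").  If
    either score is missing the stage keeps the variant (configurable via
    ``missing_passes['deleteriousness']``).
    """
    if v.sift is None or v.polyphen2_hdiv is None:
        return bool(cfg.missing_passes["deleteriousness"])
    sift_damaging = v.sift < cfg.sift_damaging_max
    polyphen_damaging = v.polyphen2_hdiv >= cfg.polyphen_damaging_min
    return sift_damaging or polyphen_damaging


def phylop_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Stage 4: positive PhyloP = conserved site."""
    if v.phylop is None:
        return bool(cfg.missing_passes["phylop"])
    return v.phylop > cfg.phylop_min


def phastcons_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Stage 5: PhastCons at or above the conserved-element threshold."""
    if v.phastcons is None:
        return bool(cfg.missing_passes["phastcons"])
    return v.phastcons >= cfg.phastcons_min


def global_frequency_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Stage 6: global allele frequency strictly below the cutoff, or unknown."""
    if v.af_global is None:
        return bool(cfg.missing_passes["af_global"])
    return v.af_global < cfg.af_global_max


def korean_frequency_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Stage 7: Korean reference-panel MAF strictly below the cutoff, or unknown."""
    if v.af_korean is None:
        return bool(cfg.missing_passes["af_korean"])
    return v.af_korean < cfg.af_korean_max


_PREDICATES: dict[str, Callable[[AnnotatedVariant, FilterConfig], bool]] = {
    "effect": effect_filter,
    "impact": impact_filter,
    "deleteriousness": deleteriousness_filter,
    "phylop": phylop_filter,
    "phastcons": phastcons_filter,
    "af_global": global_frequency_filter,
    "af_korean": korean_frequency_filter,
}


def variant_passes_stage(v: AnnotatedVariant, stage: str, cfg: FilterConfig) -> bool:
    """Evaluate one named filter stage on one variant."""
    return _PREDICATES[stage](v, cfg)


# -- trace accounting --------------------------------------------------------


class FilterTrace:
    """Per-family survivor counts after each cascade stage.

    Counts are non-increasing along the stage order within each family
    (asserted at construction).
    """

    def __init__(self, counts: Mapping[str, Mapping[str, int]]):
        self.counts: dict[str, dict[str, int]] = {}
        for family, stage_counts in counts.items():
            ordered = {}
            prev = None
            for stage in STAGES:
                if stage not in stage_counts:
                    raise ValueError(
                        f"family {family!r}: trace lacks stage {stage!r}"
                    )
                n = int(stage_counts[stage])
                if n < 0:
                    raise ValueError(f"negative survivor count at {family}/{stage}")
                if prev is not None and n > prev:
                    raise ValueError(
                        f"family {family!r}: count increases {prev} -> {n} at "
                        f"stage {stage!r}; cascade counts must be non-increasing"
                    )
                ordered[stage] = n
                prev = n
            self.counts[family] = ordered

    @property
    def families(self) -> list[str]:
        return list(self.counts)

    def stage_counts(self, stage: str) -> list[int]:
        """Counts at one stage, in family order."""
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage!r}; stages are {STAGES}")
        return [self.counts[f][stage] for f in self.counts]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (family, stage)."""
        rows = [
            {"family": fam, "stage": stage, "stage_index": i, "survivors": n}
            for fam, stage_counts in self.counts.items()
            for i, (stage, n) in enumerate(stage_counts.items())
        ]
        return pd.DataFrame(rows, columns=["family", "stage", "stage_index", "survivors"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FilterTrace):
            return NotImplemented
        return self.counts == other.counts

    def __repr__(self) -> str:
        return f"FilterTrace({len(self.counts)} families x {len(STAGES)} stages)"


def summarize_trace(trace: FilterTrace, stage: str) -> int:
    """Integer part (floor) of the mean per-family survivor count at a stage.

    Matches the convention of reporting "an average of N variants per family"
    as a whole number.
    """
    counts = trace.stage_counts(stage)
    if not counts:
        raise ValueError("trace contains no families")
    return math.floor(sum(counts) / len(counts))


# -- the cascade itself ------------------------------------------------------


@dataclass
class CascadeResult:
    """Output of a cascade run: per-family tier sets plus the trace.

    ``common`` holds survivors of stages 1-5 that failed a frequency stage
    (population-common but functionally interesting); ``rare`` holds the
    survivors of all seven stages.  The two tiers are disjoint and jointly
    equal the stage-5 survivor set.
    """

    common: dict[str, frozenset[VariantKey]]
    rare: dict[str, frozenset[VariantKey]]
    trace: FilterTrace
    config: FilterConfig

    def tier_of(self, family: str, key: VariantKey) -> str | None:
        if key in self.rare.get(family, frozenset()):
            return "rare"
        if key in self.common.get(family, frozenset()):
            return "common"
        return None


def cascade_presegregated(
    per_family_variants: Mapping[str, Sequence[AnnotatedVariant]],
    cfg: FilterConfig | None = None,
) -> CascadeResult:
    """Run filters 1-7 on variants that already co-segregate per family.

    The "raw" trace stage records the input (post-segregation) count.
    """
    cfg = cfg or FilterConfig()
    counts: dict[str, dict[str, int]] = {}
    common: dict[str, frozenset[VariantKey]] = {}
    rare: dict[str, frozenset[VariantKey]] = {}
    for family, variants in per_family_variants.items():
        survivors = list(variants)
        stage_counts = {"raw": len(survivors)}
        stage5_keys: frozenset[VariantKey] = frozenset()
        for stage in FILTER_STAGES:
            pred = _PREDICATES[stage]
            survivors = [v for v in survivors if pred(v, cfg)]
            stage_counts[stage] = len(survivors)
            if stage == "phastcons":
                stage5_keys = frozenset(v.key for v in survivors)
        rare_keys = frozenset(v.key for v in survivors)
        counts[family] = stage_counts
        rare[family] = rare_keys
        common[family] = stage5_keys - rare_keys
    return CascadeResult(common=common, rare=rare, trace=FilterTrace(counts), config=cfg)


def run_cascade(
    variants: Iterable[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    cfg: FilterConfig | None = None,
    model: str = "dominant",
    allow_hom_alt: bool = False,
) -> CascadeResult:
    """Segregation-then-filters: the full per-family prioritization.

    Segregation under the chosen inheritance model is applied before stage 1,
    so the "raw" trace counts are the per-family co-segregating variants.
    Empty input yields empty tiers and an all-zero trace, not an error.
    """
    variant_list = list(variants)
    by_key = {v.key: v for v in variant_list}
    seg = apply_segregation(
        by_key.keys(), genotypes, ped, model=model, allow_hom_alt=allow_hom_alt
    )
    per_family = {
        family: [by_key[k] for k in sorted(keys)] for family, keys in seg.items()
    }
    return cascade_presegregated(per_family, cfg)
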