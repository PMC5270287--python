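"""Synthetic multi-family exome callsets and case-control genotype cohorts.

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without real sequencing data:

* per family, a background of annotated exonic variants whose genotypes are
  Hardy–Weinberg draws from a per-variant population frequency, independent
  of affection status — background variants survive segregation only by
  chance;
* one planted causal variant per family in a designated gene, heterozygous
  in every affected member and homozygous reference in every unaffected
  member, with annotation values that clear all seven filters by
  construction (validated at generation time);
* a case-control block of per-SNP genotype counts drawn under Hardy–Weinberg
  proportions at group-specific alternate allele frequencies.

Defaults mirror the reference study design: three families of two affected
plus two unaffected members, and a validation cohort of 112 cases and 61
controls genotyped at three SNPs.  Score distributions are benign-bulk +
damaging-tail mixtures so each filter stage removes a nontrivial fraction.
All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import CaseControlCounts
from .exceptions import ConfigError
from .filters import FILTER_STAGES, FilterConfig, variant_passes_stage
from .io import write_annotated_vcf, write_counts_csv, write_pedigree
from .variants import (
    AnnotatedVariant,
    Effect,
    Genotype,
    GenotypeMatrix,
    Impact,
    PedMember,
    Pedigree,
)

__all__ = [
    "PlantedCausal",
    "CaseControlSNP",
    "SimulationConfig",
    "SimulatedCohort",
    "validate_planted",
    "simulate_family_cohort",
    "generate_family_exome",
    "simulate_case_control_counts",
    "generate_case_control_genotypes",
]

_BASES = ("A", "C", "G", "T")

#: effect -> impact mapping used for background annotation.
_EFFECT_IMPACT: dict[Effect, Impact] = {
    Effect.STOP_GAINED: Impact.HIGH,
    Effect.STOP_LOST: Impact.HIGH,
    Effect.START_LOST: Impact.HIGH,
    Effect.SPLICE_SITE_ACCEPTOR: Impact.HIGH,
    Effect.SPLICE_SITE_DONOR: Impact.HIGH,
    Effect.FRAME_SHIFT: Impact.HIGH,
    Effect.NON_SYNONYMOUS_CODING: Impact.MODERATE,
    Effect.CODON_CHANGE: Impact.MODERATE,
    Effect.CODON_INSERTION: Impact.MODERATE,
    Effect.CODON_DELETION: Impact.MODERATE,
    Effect.SYNONYMOUS_CODING: Impact.LOW,
    Effect.START_GAINED: Impact.LOW,
    Effect.UTR_5_PRIME: Impact.MODIFIER,
    Effect.UTR_3_PRIME: Impact.MODIFIER,
    Effect.INTRON: Impact.MODIFIER,
    Effect.INTERGENIC: Impact.MODIFIER,
}

#: Background effect-category probabilities (exome-shaped: coding-heavy).
DEFAULT_EFFECT_PROBS: dict[Effect, float] = {
    Effect.SYNONYMOUS_CODING: 0.34,
    Effect.NON_SYNONYMOUS_CODING: 0.40,
    Effect.INTRON: 0.08,
    Effect.UTR_3_PRIME: 0.04,
    Effect.UTR_5_PRIME: 0.02,
    Effect.START_GAINED: 0.02,
    Effect.STOP_GAINED: 0.02,
    Effect.FRAME_SHIFT: 0.02,
    Effect.SPLICE_SITE_ACCEPTOR: 0.01,
    Effect.SPLICE_SITE_DONOR: 0.01,
    Effect.CODON_DELETION: 0.02,
    Effect.CODON_INSERTION: 0.02,
}


@dataclass(frozen=True)
class PlantedCausal:
    """Specification of the planted causal variant (one position per family)."""

    gene: str = "COL6A6"
    chrom: str = "chr3"
    positions: Mapping[str, int] | None = None  # family -> pos; default derived
    ref: str = "C"
    alt: str = "T"
    aa_change: str = "R906C"
    effect: Effect = Effect.NON_SYNONYMOUS_CODING
    impact: Impact = Impact.MODERATE
    sift: float = 0.01
    polyphen2_hdiv: float = 0.99
    phylop: float = 2.5
    phastcons: float = 0.98
    af_global: float = 0.001
    af_east_asian: float = 0.002
    af_korean: float = 0.01

    def variant_for(self, family: str, family_index: int) -> AnnotatedVariant:
        if self.positions and family in self.positions:
            pos = int(self.positions[family])
        else:
            pos = 130_000_000 + 10_000 * (family_index + 1)
        return AnnotatedVariant(
            chrom=self.chrom,
            pos=pos,
            ref=self.ref,
            alt=self.alt,
            gene=self.gene,
            effect=self.effect,
            impact=self.impact,
            aa_change=self.aa_change,
            sift=self.sift,
            polyphen2_hdiv=self.polyphen2_hdiv,
            phylop=self.phylop,
            phastcons=self.phastcons,
            af_global=self.af_global,
            af_east_asian=self.af_east_asian,
            af_korean=self.af_korean,
        )


@dataclass(frozen=True)
class CaseControlSNP:
    """Alternate-allele frequencies of one validation SNP in each group."""

    snp: str
    case_af: float
    control_af: float
    ref_allele: str = "C"
    alt_allele: str = "T"

    def __post_init__(self) -> None:
        for name in ("case_af", "control_af"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{self.snp}: {name}={v} outside [0, 1]")


def _default_case_control_snps() -> tuple[CaseControlSNP, ...]:
    # Frequencies shaped like the three validated COL6A6 SNPs.
    return (
        CaseControlSNP("snp1", case_af=0.156, control_af=0.189, ref_allele="G", alt_allele="A"),
        CaseControlSNP("snp2", case_af=0.112, control_af=0.115),
        CaseControlSNP("snp3", case_af=0.018, control_af=0.008),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort generator (single global seed).

    The family block emulates the discovery design (three 2-affected /
    2-unaffected families); the case-control block the validation design
    (112 cases, 61 controls).
    """

    n_families: int = 3
    n_affected: int = 2
    n_unaffected: int = 2
    n_background_variants: int = 2_000
    n_genes: int = 800
    effect_probs: Mapping[Effect, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROBS)
    )
    #: fraction of damaging draws in each score mixture
    sift_damaging_frac: float = 0.25
    polyphen_damaging_frac: float = 0.30
    phylop_positive_frac: float = 0.65
    phastcons_conserved_frac: float = 0.50
    #: per-score probability that the annotation is missing
    missing_rate: float = 0.10
    #: beta parameters of the population allele-frequency distribution
    af_beta: tuple[float, float] = (0.6, 3.0)
    planted: PlantedCausal | None = field(default_factory=PlantedCausal)
    n_cases: int = 112
    n_controls: int = 61
    case_control_snps: tuple[CaseControlSNP, ...] = field(
        default_factory=_default_case_control_snps
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = dict(self.effect_probs)
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"effect probabilities sum to {total}, expected 1")
        for name in (
            "sift_damaging_frac",
            "polyphen_damaging_frac",
            "phylop_positive_frac",
            "phastcons_conserved_frac",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        object.__setattr__(self, "effect_probs", probs)
        object.__setattr__(
            self, "case_control_snps", tuple(self.case_control_snps)
        )

    def family_ids(self) -> list[str]:
        return [f"FAM{i + 1}" for i in range(self.n_families)]


def validate_planted(planted: PlantedCausal, filter_cfg: FilterConfig | None = None) -> None:
    """Check that the planted spec clears every filter stage; raise a
    ConfigError naming the first violated stage otherwise."""
    cfg = filter_cfg or FilterConfig()
    probe = planted.variant_for("_probe", 0)
    for stage in FILTER_STAGES:
        if not variant_passes_stage(probe, stage, cfg):
            raise ConfigError(
                f"planted causal variant fails filter stage {stage!r} under the "
                f"configured thresholds"
            )


@dataclass
class SimulatedCohort:
    """In-memory result of a family-cohort simulation."""

    variants_by_family: dict[str, list[AnnotatedVariant]]
    genotypes_by_family: dict[str, GenotypeMatrix]
    pedigree: Pedigree
    truth: pd.DataFrame  # planted gene/positions per family
    population_af: dict[str, dict] = field(default_factory=dict)

    def merged_genotypes(self) -> GenotypeMatrix:
        return GenotypeMatrix.merge(self.genotypes_by_family.values())

    def all_variants(self) -> list[AnnotatedVariant]:
        seen: set = set()
        out: list[AnnotatedVariant] = []
        for fam in self.variants_by_family:
            for v in self.variants_by_family[fam]:
                if v.key not in seen:
                    seen.add(v.key)
                    out.append(v)
        return out


def _sample_scores(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> dict:
    """Vectorized mixture draws for the four scores plus frequencies."""
    def mixture(frac_special, special_lo, special_hi, bulk_lo, bulk_hi):
        special = rng.random(n) < frac_special
        vals = np.where(
            special,
            rng.uniform(special_lo, special_hi, n),
            rng.uniform(bulk_lo, bulk_hi, n),
        )
        return vals

    sift = mixture(cfg.sift_damaging_frac, 0.0, 0.05, 0.05, 1.0)
    polyphen = mixture(cfg.polyphen_damaging_frac, 0.453, 1.0, 0.0, 0.453)
    phylop = np.where(
        rng.random(n) < cfg.phylop_positive_frac,
        rng.uniform(0.01, 6.0, n),
        rng.uniform(-3.0, 0.0, n),
    )
    phastcons = mixture(cfg.phastcons_conserved_frac, 0.2, 1.0, 0.0, 0.2)
    return {
        "sift": np.round(sift, 4),
        "polyphen2_hdiv": np.round(polyphen, 4),
        "phylop": np.round(phylop, 4),
        "phastcons": np.round(phastcons, 4),
    }


def simulate_family_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate the in-memory multi-family cohort.

    Deterministic given ``cfg.seed``: identical configs produce identical
    cohorts (and, through :func:`generate_family_exome`, byte-identical
    files).
    """
    if cfg.planted is not None:
        validate_planted(cfg.planted)
    rng = np.random.default_rng(cfg.seed)
    families = cfg.family_ids()

    # shared gene map: gene -> (chrom, window start), identical across families
    gene_names = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    gene_chrom_idx = rng.integers(0, 22, cfg.n_genes)
    gene_start = rng.integers(1_000_000, 200_000_000, cfg.n_genes)

    members: list[PedMember] = []
    variants_by_family: dict[str, list[AnnotatedVariant]] = {}
    genotypes_by_family: dict[str, GenotypeMatrix] = {}
    population_af: dict[str, dict] = {}
    truth_rows: list[dict] = []

    for fam_idx, family in enumerate(families):
        sample_ids: list[str] = []
        affected_flags: list[bool] = []
        roles = (
            [("FATHER", True), ("MOTHER", False)]
            if cfg.n_affected >= 1 and cfg.n_unaffected >= 1
            else []
        )
        # Affection pattern: one affected parent, one unaffected parent, the
        # rest of the affected/unaffected slots filled by children.
        n_aff_children = cfg.n_affected - 1
        n_unaff_children = cfg.n_unaffected - 1
        for label, affected in roles:
            sample_ids.append(f"{family}_{label}")
            affected_flags.append(affected)
        for i in range(n_aff_children):
            sample_ids.append(f"{family}_CHILD{i + 1}")
            affected_flags.append(True)
        for i in range(n_unaff_children):
            sample_ids.append(f"{family}_CHILD{n_aff_children + i + 1}")
            affected_flags.append(False)
        father = f"{family}_FATHER" if roles else "0"
        mother = f"{family}_MOTHER" if roles else "0"
        for sid, affected in zip(sample_ids, affected_flags):
            is_parent = sid.endswith(("FATHER", "MOTHER"))
            members.append(
                PedMember(
                    family=family,
                    individual=sid,
                    father="0" if is_parent else father,
                    mother="0" if is_parent else mother,
                    sex=1 if sid.endswith("FATHER") else 2 if sid.endswith("MOTHER") else int(rng.integers(1, 3)),
                    affected=affected,
                    role="father" if sid.endswith("FATHER") else "mother" if sid.endswith("MOTHER") else "child",
                )
            )

        n = cfg.n_background_variants
        gene_idx = rng.integers(0, cfg.n_genes, n)
        offsets = rng.integers(1, 50_000, n)
        pos = gene_start[gene_idx] + offsets
        chroms = [f"chr{gene_chrom_idx[g] + 1}" for g in gene_idx]
        ref_idx = rng.integers(0, 4, n)
        alt_shift = rng.integers(1, 4, n)
        effects = rng.choice(
            [e.value for e in cfg.effect_probs],
            size=n,
            p=list(cfg.effect_probs.values()),
        )
        scores = _sample_scores(cfg, rng, n)
        p_pop = rng.beta(*cfg.af_beta, n)
        af_global = np.round(p_pop, 4)
        af_korean = np.round(np.clip(p_pop + rng.normal(0, 0.01, n), 0, 1), 4)
        missing = {
            name: rng.random(n) < cfg.missing_rate
            for name in ("sift", "polyphen2_hdiv", "phylop", "phastcons",
                         "af_global", "af_korean")
        }

        fam_variants: list[AnnotatedVariant] = []
        seen_keys: set = set()
        rows: list[list[int]] = []
        af_map: dict = {}
        n_samples = len(sample_ids)
        geno_draws = rng.binomial(2, p_pop[:, None], size=(n, n_samples))
        for i in range(n):
            ref = _BASES[ref_idx[i]]
            alt = _BASES[(ref_idx[i] + alt_shift[i]) % 4]
            effect = Effect(effects[i])
            key = (chroms[i], int(pos[i]), ref, alt)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            var = AnnotatedVariant(
                chrom=chroms[i],
                pos=int(pos[i]),
                ref=ref,
                alt=alt,
                gene=gene_names[gene_idx[i]],
                effect=effect,
                impact=_EFFECT_IMPACT[effect],
                sift=None if missing["sift"][i] else float(scores["sift"][i]),
                polyphen2_hdiv=None if missing["polyphen2_hdiv"][i] else float(scores["polyphen2_hdiv"][i]),
                phylop=None if missing["phylop"][i] else float(scores["phylop"][i]),
                phastcons=None if missing["phastcons"][i] else float(scores["phastcons"][i]),
                af_global=None if missing["af_global"][i] else float(af_global[i]),
                af_korean=None if missing["af_korean"][i] else float(af_korean[i]),
            )
            fam_variants.append(var)
            af_map[var.key] = float(p_pop[i])
            rows.append([int(g) for g in geno_draws[i]])

        if cfg.planted is not None:
            planted_var = cfg.planted.variant_for(family, fam_idx)
            if planted_var.key in seen_keys:  # vanishingly unlikely; keep total
                fam_variants = [v for v in fam_variants if v.key != planted_var.key]
            fam_variants.append(planted_var)
            rows.append(
                [
                    int(Genotype.HET if affected else Genotype.HOM_REF)
                    for affected in affected_flags
                ]
            )
            af_map[planted_var.key] = None
            truth_rows.append(
                {
                    "family": family,
                    "gene": cfg.planted.gene,
                    "chrom": planted_var.chrom,
                    "pos": planted_var.pos,
                }
            )

        # sort variants by genomic coordinate for well-formed VCF output
        order = sorted(range(len(fam_variants)), key=lambda i: fam_variants[i].key)
        fam_variants = [fam_variants[i] for i in order]
        rows = [rows[i] for i in order]
        calls = np.asarray(rows, dtype=np.int8) if rows else np.empty(
            (0, n_samples), dtype=np.int8
        )
        variants_by_family[family] = fam_variants
        genotypes_by_family[family] = GenotypeMatrix(
            [v.key for v in fam_variants], sample_ids, calls
        )
        population_af[family] = af_map

    truth = pd.DataFrame(truth_rows, columns=["family", "gene", "chrom", "pos"])
    return SimulatedCohort(
        variants_by_family=variants_by_family,
        genotypes_by_family=genotypes_by_family,
        pedigree=Pedigree(members),
        truth=truth,
        population_af=population_af,
    )


def generate_family_exome(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write one VCF per family plus PED and truth CSV.

    Returns the written paths keyed by artifact name ('vcf_FAM1', ...,
    'ped', 'truth').  Same config (and seed) => byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_family_cohort(cfg)
    paths: dict[str, Path] = {}
    for family, variants in cohort.variants_by_family.items():
        vcf_path = out_dir / f"{family.lower()}.vcf"
        write_annotated_vcf(vcf_path, variants, cohort.genotypes_by_family[family])
        paths[f"vcf_{family}"] = vcf_path
    paths["ped"] = write_pedigree(out_dir / "cohort.ped", cohort.pedigree)
    truth_path = out_dir / "truth.csv"
    cohort.truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    return paths


def simulate_case_control_counts(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CaseControlCounts]:
    """Draw per-SNP genotype counts under Hardy–Weinberg proportions at each
    group's alternate-allele frequency."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out: list[CaseControlCounts] = []
    for snp in cfg.case_control_snps:
        counts = {}
        for group, n, p in (
            ("case", cfg.n_cases, snp.case_af),
            ("control", cfg.n_controls, snp.control_af),
        ):
            probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
            counts[group] = tuple(int(x) for x in rng.multinomial(n, probs))
        out.append(
            CaseControlCounts(
                snp=snp.snp,
                ref_allele=snp.ref_allele,
                alt_allele=snp.alt_allele,
                case=counts["case"],
                control=counts["control"],
            )
        )
    return out


def generate_case_control_genotypes(
    cfg: SimulationConfig, out_path: str | Path
) -> Path:
    """Simulate the case-control block and write it in the counts CSV schema."""
    counts = simulate_case_control_counts(cfg)
    return write_counts_csv(out_path, counts)
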