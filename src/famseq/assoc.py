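"""Case-control association statistics for candidate SNPs.

Validation cohorts are summarized as per-SNP genotype counts in cases and
controls.  The module reproduces the standard candidate-SNP table: allele and
genotype frequency percentages, 2x2 collapses under allelic / dominant /
recessive models, and odds ratios with Woolf (log) 95% confidence intervals.
Zero cells are handled with the Haldane–Anscombe correction (add 0.5 to every
cell), flagged on the result and configurable.

An exact Hardy–Weinberg equilibrium test (conditional on allele counts) is
included to sanity-check genotype tables; it is used for cohort QC and for
validating simulated cohorts rather than reported as an association result.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact, norm

from .exceptions import UndefinedOddsRatioError

__all__ = [
    "MODELS",
    "CaseControlCounts",
    "AssociationResult",
    "genotype_to_allele_counts",
    "frequency_table",
    "collapse_model",
    "odds_ratio_ci",
    "association",
    "hwe_exact_check",
]

MODELS = ("allelic", "dominant", "recessive")

#: genotype counts are ordered (hom_ref, het, hom_alt)
GenotypeCounts = tuple[int, int, int]


@dataclass(frozen=True)
class CaseControlCounts:
    """Genotype counts for one SNP in cases and controls."""

    snp: str
    ref_allele: str
    alt_allele: str
    case: GenotypeCounts
    control: GenotypeCounts

    def __post_init__(self) -> None:
        for group, counts in (("case", self.case), ("control", self.control)):
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ValueError(
                    f"{self.snp}/{group}: genotype counts must be three "
                    f"non-negative integers, got {counts}"
                )
            object.__setattr__(self, group, tuple(int(c) for c in counts))

    @property
    def n_cases(self) -> int:
        return sum(self.case)

    @property
    def n_controls(self) -> int:
        return sum(self.control)


def genotype_to_allele_counts(g: GenotypeCounts) -> tuple[int, int]:
    """(ref, alt) allele counts from (hom_ref, het, hom_alt) genotype counts.

    Each sample contributes two alleles, so the totals always sum to twice
    the genotype total.
    """
    hom_ref, het, hom_alt = g
    return (2 * hom_ref + het, 2 * hom_alt + het)


def _pct(count: int, denom: int) -> float:
    """Percentage with half-up rounding to one decimal (the convention of
    printed frequency tables: 22.95 -> 23.0, 1.79 -> 1.8)."""
    if denom == 0:
        return 0.0
    q = (Decimal(count) * 100) / Decimal(denom)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def frequency_table(cc: CaseControlCounts) -> dict:
    """Allele and genotype counts and percentages per group.

    Returns a nested dict
    ``{group: {"genotype": {label: (count, pct)}, "allele": {label: (count, pct)}}}``
    with genotype labels built from the allele letters (e.g. GG/GA/AA) and
    percentages half-up rounded to one decimal.
    """
    r, a = cc.ref_allele, cc.alt_allele
    genotype_labels = (r + r, r + a, a + a)
    out: dict[str, dict] = {}
    for group, counts in (("control", cc.control), ("case", cc.case)):
        n = sum(counts)
        ref_n, alt_n = genotype_to_allele_counts(counts)
        out[group] = {
            "n": n,
            "genotype": {
                label: (count, _pct(count, n))
                for label, count in zip(genotype_labels, counts)
            },
            "allele": {
                r: (ref_n, _pct(ref_n, 2 * n)),
                a: (alt_n, _pct(alt_n, 2 * n)),
            },
        }
    return out


def collapse_model(cc: CaseControlCounts, model: str) -> tuple[int, int, int, int]:
    """Collapse genotype counts to a 2x2 exposure table (a, b, c, d).

    a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.  Exposure is: the alternate allele (allelic
    model, counting alleles), carrying >=1 alternate allele (dominant), or
    being homozygous alternate (recessive).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if model == "allelic":
        case_ref, case_alt = genotype_to_allele_counts(cc.case)
        ctrl_ref, ctrl_alt = genotype_to_allele_counts(cc.control)
        return (case_alt, case_ref, ctrl_alt, ctrl_ref)
    (case_rr, case_ra, case_aa) = cc.case
    (ctrl_rr, ctrl_ra, ctrl_aa) = cc.control
    if model == "dominant":
        return (case_ra + case_aa, case_rr, ctrl_ra + ctrl_aa, ctrl_rr)
    return (case_aa, case_rr + case_ra, ctrl_aa, ctrl_rr + ctrl_ra)


@dataclass(frozen=True)
class AssociationResult:
    """Odds ratio with Woolf 95% CI for one SNP under one genetic model."""

    snp: str
    model: str
    table: tuple[int, int, int, int]  # (a, b, c, d) as in collapse_model
    odds_ratio: float
    ci_low: float
    ci_high: float
    correction_applied: bool
    alpha: float = 0.05
    fisher_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.odds_ratio > 0):
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")


def odds_ratio_ci(
    table: Sequence[int],
    alpha: float = 0.05,
    correction: str = "haldane",
    snp: str = "",
    model: str = "allelic",
    fisher: bool = False,
) -> AssociationResult:
    """Cross-product odds ratio with a Woolf log-interval CI.

    OR = (a*d)/(b*c).  With ``correction='haldane'`` (default) a table with
    any zero cell gets 0.5 added to all four cells before both the OR and the
    CI are computed, and ``correction_applied`` is set.  With
    ``correction='none'`` a zero cell raises
    :class:`UndefinedOddsRatioError` rather than returning 0/inf/NaN.
    ``fisher=True`` additionally attaches a two-sided Fisher exact p-value
    (computed on the uncorrected counts).
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")
    if correction not in ("haldane", "none"):
        raise ValueError(f"correction must be 'haldane' or 'none', got {correction!r}")
    corrected = False
    af, bf, cf, df = float(a), float(b), float(c), float(d)
    if min(a, b, c, d) == 0:
        if correction == "none":
            raise UndefinedOddsRatioError(
                f"table {table} has a zero cell; odds ratio undefined without "
                f"continuity correction"
            )
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (af * df) / (bf * cf)
    se = float(np.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df))
    z = float(norm.ppf(1 - alpha / 2))
    log_or = float(np.log(or_))
    ci_low = float(np.exp(log_or - z * se))
    ci_high = float(np.exp(log_or + z * se))
    fisher_p = None
    if fisher:
        fisher_p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return AssociationResult(
        snp=snp,
        model=model,
        table=(a, b, c, d),
        odds_ratio=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        correction_applied=corrected,
        alpha=alpha,
        fisher_p=fisher_p,
    )


def association(
    cc: CaseControlCounts,
    model: str,
    alpha: float = 0.05,
    correction: str = "haldane",
    fisher: bool = False,
) -> AssociationResult:
    """Collapse one SNP under one genetic model and compute its OR and CI."""
    table = collapse_model(cc, model)
    return odds_ratio_ci(
        table, alpha=alpha, correction=correction, snp=cc.snp, model=model,
        fisher=fisher,
    )


def hwe_exact_check(g: GenotypeCounts) -> float:
    """Exact conditional test of Hardy–Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more probable than the observed one
    (point-mass ordering).  Returns 1.0 for degenerate tables (zero samples,
    or a monomorphic site).
    """
    hom_ref, het, hom_alt = (int(x) for x in g)
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    if n == 0:
        return 1.0
    n_alt = 2 * hom_alt + het
    minor = min(n_alt, 2 * n - n_alt)
    if minor == 0:
        return 1.0
    # possible heterozygote counts share the parity of the minor allele count
    hets = np.arange(minor % 2, minor + 1, 2)
    homs_minor = (minor - hets) // 2
    homs_major = n - hets - homs_minor
    log_w = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homs_minor + 1)
        - gammaln(homs_major + 1)
    )
    log_p = log_w - logsumexp(log_w)
    probs = np.exp(log_p)
    observed = np.where(hets == het)[0]
    if observed.size == 0:  # inconsistent het parity cannot occur for valid input
        raise ValueError(f"genotype counts {g} inconsistent with allele counts")
    p_obs = probs[observed[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
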