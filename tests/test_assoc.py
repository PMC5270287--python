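"""Allele/genotype frequency tables, 2x2 collapses, odds ratios, exact HWE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famseq.assoc import (
    CaseControlCounts,
    association,
    collapse_model,
    frequency_table,
    genotype_to_allele_counts,
    hwe_exact_check,
    odds_ratio_ci,
)
from famseq.datasets import case_control_counts
from famseq.exceptions import UndefinedOddsRatioError

REFERENCE = {cc.snp: cc for cc in case_control_counts()}


class TestAlleleCounts:
    @pytest.mark.parametrize(
        "genotypes,expected",
        [
            ((47, 14, 0), (108, 14)),   # control CC/CT/TT -> C/T
            ((89, 21, 2), (199, 25)),
            ((50, 0, 0), (100, 0)),     # all HOM_REF: no alt alleles
        ],
    )
    def test_counting(self, genotypes, expected):
        assert genotype_to_allele_counts(genotypes) == expected

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
        )
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_alleles_sum_to_twice_genotype_total(self, g):
        ref, alt = genotype_to_allele_counts(g)
        assert ref + alt == 2 * sum(g)


class TestFrequencyTable:
    def test_reference_percentages(self):
        ft = frequency_table(REFERENCE["rs16830494"])
        assert ft["control"]["allele"]["A"] == (23, 18.9)
        assert ft["control"]["genotype"]["GG"] == (39, 63.9)
        ft = frequency_table(REFERENCE["rs59021909"])
        assert ft["case"]["genotype"]["TT"] == (2, 1.8)
        assert ft["case"]["allele"]["T"] == (25, 11.2)
        assert ft["control"]["genotype"]["CT"] == (14, 23.0)  # 22.95 rounds half-up
        ft = frequency_table(REFERENCE["rs200963433"])
        assert ft["case"]["genotype"]["CT"] == (4, 3.6)

    def test_single_genotype_class(self):
        cc = CaseControlCounts("s", "A", "G", case=(10, 0, 0), control=(5, 0, 0))
        ft = frequency_table(cc)
        assert ft["case"]["genotype"]["AA"] == (10, 100.0)
        assert ft["case"]["genotype"]["AG"] == (0, 0.0)

    def test_percentages_sum_to_100_within_rounding(self):
        for cc in case_control_counts():
            ft = frequency_table(cc)
            for group in ("case", "control"):
                for block in ("genotype", "allele"):
                    total = sum(p for _, p in ft[group][block].values())
                    # three classes each rounded to 0.1 can drift by 3 * 0.05
                    assert abs(total - 100.0) <= 0.15


class TestCollapseModel:
    def test_allelic(self):
        assert collapse_model(REFERENCE["rs200963433"], "allelic") == (4, 220, 1, 121)

    def test_dominant(self):
        assert collapse_model(REFERENCE["rs16830494"], "dominant") == (32, 79, 22, 39)

    def test_recessive(self):
        assert collapse_model(REFERENCE["rs59021909"], "recessive") == (2, 110, 0, 61)

    def test_all_hom_ref_gives_zero_exposure(self):
        cc = CaseControlCounts("s", "C", "T", case=(10, 0, 0), control=(5, 0, 0))
        for model in ("allelic", "dominant", "recessive"):
            a, _, c, _ = collapse_model(cc, model)
            assert a == 0 and c == 0

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            collapse_model(REFERENCE["rs16830494"], "overdominant")


class TestOddsRatio:
    def test_rare_variant_allelic_or(self):
        res = odds_ratio_ci((4, 220, 1, 121))
        assert res.odds_ratio == pytest.approx(2.2, abs=0.005)
        assert not res.correction_applied

    def test_balanced_table_or_one(self):
        res = odds_ratio_ci((10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_haldane_correction_on_zero_cell(self):
        # (2.5 * 61.5) / (110.5 * 0.5) computed by hand
        res = odds_ratio_ci((2, 110, 0, 61))
        assert res.correction_applied
        assert res.odds_ratio == pytest.approx((2.5 * 61.5) / (110.5 * 0.5))
        assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)

    def test_zero_cell_without_correction_raises(self):
        with pytest.raises(UndefinedOddsRatioError):
            odds_ratio_ci((2, 110, 0, 61), correction="none")

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_transposing_groups_inverts_or(self, table):
        a, b, c, d = table
        res = odds_ratio_ci((a, b, c, d))
        inv = odds_ratio_ci((c, d, a, b))
        assert res.odds_ratio * inv.odds_ratio == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0 / inv.ci_high)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0

    def test_woolf_interval_matches_statsmodels_on_zero_free_table(self):
        sm = pytest.importorskip("statsmodels.api")
        table = (32, 79, 22, 39)
        res = odds_ratio_ci(table)
        t22 = sm.stats.Table2x2(np.array(table).reshape(2, 2))
        assert res.odds_ratio == pytest.approx(t22.oddsratio)
        lo, hi = t22.oddsratio_confint(0.05)
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)

    def test_fisher_p_attached_on_request(self):
        res = association(REFERENCE["rs16830494"], "dominant", fisher=True)
        assert res.fisher_p is not None and 0 <= res.fisher_p <= 1


class TestHweExact:
    def test_perfect_hwe_point_mass_gives_p_one(self):
        assert hwe_exact_check((25, 50, 25)) == pytest.approx(1.0)

    def test_all_het_is_extreme(self):
        assert hwe_exact_check((0, 20, 0)) < 0.01

    def test_single_sample_has_no_power(self):
        assert hwe_exact_check((0, 1, 0)) == 1.0

    def test_monomorphic_and_empty_tables(self):
        assert hwe_exact_check((30, 0, 0)) == 1.0
        assert hwe_exact_check((0, 0, 0)) == 1.0

    @pytest.mark.parametrize("g", [(20, 10, 5), (5, 25, 5), (12, 2, 9)])
    def test_matches_permutation_oracle(self, g):
        """Independent oracle: shuffle the 2n alleles into pairs and use the
        empirical heterozygote-count distribution."""
        rng = np.random.default_rng(123)
        hom_ref, het, hom_alt = g
        n = sum(g)
        alleles = np.array([0] * (2 * hom_ref + het) + [1] * (2 * hom_alt + het))
        n_rep = 40_000
        hets = np.empty(n_rep, dtype=int)
        for r in range(n_rep):
            rng.shuffle(alleles)
            pairs = alleles.reshape(n, 2)
            hets[r] = int((pairs[:, 0] != pairs[:, 1]).sum())
        values, freqs = np.unique(hets, return_counts=True)
        probs = freqs / n_rep
        p_obs = probs[values == het][0] if het in values else 0.0
        p_mc = probs[probs <= p_obs * (1 + 1e-9)].sum()
        assert hwe_exact_check(g) == pytest.approx(p_mc, abs=0.02)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_check((-1, 2, 3))
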