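"""The seven filter predicates, the cascade, and the trace accounting."""

import numpy as np
import pytest

from famseq.datasets import family_variants, reference_trace
from famseq.filters import (
    FILTER_STAGES,
    FilterConfig,
    FilterTrace,
    STAGES,
    cascade_presegregated,
    deleteriousness_filter,
    effect_filter,
    global_frequency_filter,
    impact_filter,
    korean_frequency_filter,
    phastcons_filter,
    phylop_filter,
    summarize_trace,
)
from famseq.variants import Effect

from conftest import make_variant, random_variants

CFG = FilterConfig()


# -- independent single-pass oracle ------------------------------------------
# A deliberately naive re-statement of the filter rules, kept separate from
# the cascade implementation it checks.

def oracle_stage_pass(v, stage):
    if stage == "effect":
        return v.effect.value in {
            "NON_SYNONYMOUS_CODING", "STOP_GAINED", "STOP_LOST", "START_LOST",
            "SPLICE_SITE_ACCEPTOR", "SPLICE_SITE_DONOR", "FRAME_SHIFT",
            "CODON_CHANGE", "CODON_INSERTION", "CODON_DELETION",
            "CODON_CHANGE_PLUS_CODON_INSERTION", "CODON_CHANGE_PLUS_CODON_DELETION",
        }
    if stage == "impact":
        return v.impact.value in ("HIGH", "MODERATE")
    if stage == "deleteriousness":
        if v.sift is None or v.polyphen2_hdiv is None:
            return True
        return not (v.sift >= 0.05 and v.polyphen2_hdiv < 0.453)
    if stage == "phylop":
        return v.phylop is None or v.phylop > 0
    if stage == "phastcons":
        return v.phastcons is None or v.phastcons >= 0.2
    if stage == "af_global":
        return v.af_global is None or v.af_global < 0.01
    if stage == "af_korean":
        return v.af_korean is None or v.af_korean < 0.02
    raise AssertionError(stage)


def oracle_counts(variants):
    counts = {"raw": len(variants)}
    survivors = list(variants)
    for stage in FILTER_STAGES:
        survivors = [v for v in survivors if oracle_stage_pass(v, stage)]
        counts[stage] = len(survivors)
    return counts


def oracle_tiers(variants):
    s5 = [
        v for v in variants
        if all(oracle_stage_pass(v, s) for s in FILTER_STAGES[:5])
    ]
    rare = {
        v.key for v in s5
        if oracle_stage_pass(v, "af_global") and oracle_stage_pass(v, "af_korean")
    }
    return {v.key for v in s5} - rare, rare


class TestPredicates:
    @pytest.mark.parametrize(
        "effect,expected",
        [
            (Effect.NON_SYNONYMOUS_CODING, True),   # missense survives
            (Effect.STOP_GAINED, True),              # nonsense survives
            (Effect.FRAME_SHIFT, True),
            (Effect.SYNONYMOUS_CODING, False),
            (Effect.INTERGENIC, False),
        ],
    )
    def test_effect_filter_keep_set(self, effect, expected):
        v = make_variant(effect=effect, impact="MODERATE")
        assert effect_filter(v, CFG) is expected

    @pytest.mark.parametrize(
        "impact,expected",
        [("HIGH", True), ("MODERATE", True), ("LOW", False), ("MODIFIER", False)],
    )
    def test_impact_filter_keep_set(self, impact, expected):
        assert impact_filter(make_variant(impact=impact), CFG) is expected

    @pytest.mark.parametrize(
        "sift,polyphen,expected",
        [
            (0.04, 0.272, True),    # SIFT damaging alone suffices
            (0.77, 0.688, True),    # PolyPhen possibly-damaging alone suffices
            (0.11, None, True),     # one score absent -> retained
            (None, 0.10, True),
            (0.60, 0.10, False),    # both present, both benign
            (0.05, 0.452, False),   # boundaries: SIFT 0.05 tolerated, PP 0.452 benign
            (0.0499, 0.0, True),    # just below the SIFT cutoff
            (1.0, 0.453, True),     # PP exactly at possibly-damaging
        ],
    )
    def test_deleteriousness_filter(self, sift, polyphen, expected):
        v = make_variant(sift=sift, polyphen2_hdiv=polyphen)
        assert deleteriousness_filter(v, CFG) is expected

    @pytest.mark.parametrize(
        "phylop,expected",
        [(0.049, True), (-1.0, False), (0.0, False), (None, True)],
    )
    def test_phylop_filter(self, phylop, expected):
        assert phylop_filter(make_variant(phylop=phylop), CFG) is expected

    @pytest.mark.parametrize(
        "phastcons,expected",
        [(0.995, True), (0.2, True), (0.19, False), (None, True)],
    )
    def test_phastcons_filter(self, phastcons, expected):
        assert phastcons_filter(make_variant(phastcons=phastcons), CFG) is expected

    @pytest.mark.parametrize(
        "af,expected",
        [(0.0014, True), (0.12, False), (0.01, False), (None, True)],
    )
    def test_global_frequency_filter(self, af, expected):
        assert global_frequency_filter(make_variant(af_global=af), CFG) is expected

    @pytest.mark.parametrize(
        "af,expected",
        [(0.017, True), (0.02, False), (0.188, False), (None, True)],
    )
    def test_korean_frequency_filter(self, af, expected):
        assert korean_frequency_filter(make_variant(af_korean=af), CFG) is expected

    def test_missing_can_be_configured_to_fail(self):
        cfg = FilterConfig(missing_passes={"phylop": False})
        assert phylop_filter(make_variant(phylop=None), cfg) is False
        assert phylop_filter(make_variant(phylop=1.0), cfg) is True


class TestCascade:
    def test_matches_brute_force_oracle_on_random_input(self):
        rng = np.random.default_rng(42)
        per_family = {
            "F1": random_variants(rng, 800),
            "F2": random_variants(rng, 800),
        }
        result = cascade_presegregated(per_family)
        for fam, variants in per_family.items():
            assert result.trace.counts[fam] == oracle_counts(variants)
            common, rare = oracle_tiers(variants)
            assert result.common[fam] == common
            assert result.rare[fam] == rare

    def test_empty_input_gives_zero_trace(self):
        result = cascade_presegregated({"F1": []})
        assert all(n == 0 for n in result.trace.counts["F1"].values())
        assert result.common["F1"] == frozenset() == result.rare["F1"]

    def test_family_a_candidate_rows_split_11_common_2_rare(self):
        variants = [v for v, _ in family_variants("A", harmonized=True)]
        result = cascade_presegregated({"A": variants})
        assert len(result.common["A"]) == 11
        assert len(result.rare["A"]) == 2
        by_key = {v.key: v for v in variants}
        rare_genes = sorted(by_key[k].gene for k in result.rare["A"])
        assert rare_genes == ["COL6A6", "DNAH17"]

    def test_tiers_partition_stage5_survivors(self):
        rng = np.random.default_rng(7)
        variants = random_variants(rng, 500)
        result = cascade_presegregated({"F": variants})
        common, rare = result.common["F"], result.rare["F"]
        assert not (common & rare)
        s5 = {
            v.key for v in variants
            if all(oracle_stage_pass(v, s) for s in FILTER_STAGES[:5])
        }
        assert common | rare == s5

    def test_trace_monotone_nonincreasing(self):
        rng = np.random.default_rng(3)
        result = cascade_presegregated({"F": random_variants(rng, 400)})
        counts = [result.trace.counts["F"][s] for s in STAGES]
        assert counts == sorted(counts, reverse=True)

    def test_increasing_trace_rejected_at_construction(self):
        counts = dict.fromkeys(STAGES, 5)
        counts["af_korean"] = 6
        with pytest.raises(ValueError, match="non-increasing"):
            FilterTrace({"F": counts})


class TestTraceSummary:
    def test_floor_of_mean(self):
        trace = reference_trace()
        assert summarize_trace(trace, "phastcons") == 176
        assert summarize_trace(trace, "af_global") == 48
        assert summarize_trace(trace, "af_korean") == 44

    def test_constant_counts(self):
        trace = FilterTrace(
            {f: dict.fromkeys(STAGES, 10) for f in ("x", "y", "z")}
        )
        assert summarize_trace(trace, "phastcons") == 10

    def test_unknown_stage_rejected(self):
        with pytest.raises(KeyError):
            summarize_trace(reference_trace(), "filter9")


class TestFilterConfig:
    def test_serialization_round_trip(self):
        cfg = FilterConfig(af_korean_max=0.05, missing_passes={"af_global": False})
        assert FilterConfig.from_dict(cfg.to_dict()) == cfg

    def test_out_of_range_threshold_rejected(self):
        from famseq.exceptions import ConfigError

        with pytest.raises(ConfigError, match="sift_damaging_max"):
            FilterConfig(sift_damaging_max=1.5)
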