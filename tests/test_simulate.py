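"""The synthetic cohort generator: determinism, planted-variant guarantees,
and the statistical contracts of the background model."""

import filecmp

import numpy as np
import pytest

from famseq.assoc import hwe_exact_check, odds_ratio_ci
from famseq.exceptions import ConfigError
from famseq.filters import FilterConfig
from famseq.segregation import apply_segregation
from famseq.simulate import (
    CaseControlSNP,
    PlantedCausal,
    SimulationConfig,
    generate_family_exome,
    simulate_case_control_counts,
    simulate_family_cohort,
    validate_planted,
)
from famseq.variants import Genotype


class TestPlantedSpec:
    def test_default_spec_clears_every_filter(self):
        validate_planted(PlantedCausal())

    @pytest.mark.parametrize(
        "override,stage",
        [
            ({"sift": 0.5, "polyphen2_hdiv": 0.1}, "deleteriousness"),
            ({"phylop": -2.0}, "phylop"),
            ({"phastcons": 0.05}, "phastcons"),
            ({"af_global": 0.2}, "af_global"),
            ({"af_korean": 0.5}, "af_korean"),
            ({"effect": "SYNONYMOUS_CODING", "impact": "LOW"}, "effect"),
        ],
    )
    def test_filter_violating_spec_names_the_stage(self, override, stage):
        with pytest.raises(ConfigError, match=stage):
            validate_planted(PlantedCausal(**override))

    def test_generation_rejects_bad_planted_spec(self):
        cfg = SimulationConfig(
            seed=0, n_background_variants=10, planted=PlantedCausal(phastcons=0.01)
        )
        with pytest.raises(ConfigError, match="phastcons"):
            simulate_family_cohort(cfg)


class TestFamilyCohort:
    def test_planted_variant_genotypes_follow_dominant_pattern(self, small_cohort):
        cfg, cohort = small_cohort
        for row in cohort.truth.itertuples():
            key = (row.chrom, row.pos, cfg.planted.ref, cfg.planted.alt)
            gm = cohort.genotypes_by_family[row.family]
            ped = cohort.pedigree
            for s in ped.affected(row.family):
                assert gm.call(key, s) is Genotype.HET
            for s in ped.unaffected(row.family):
                assert gm.call(key, s) is Genotype.HOM_REF

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_background_variants=150)
        p1 = generate_family_exome(cfg, tmp_path / "run1")
        p2 = generate_family_exome(cfg, tmp_path / "run2")
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        a = generate_family_exome(
            SimulationConfig(seed=1, n_background_variants=100), tmp_path / "a"
        )
        b = generate_family_exome(
            SimulationConfig(seed=2, n_background_variants=100), tmp_path / "b"
        )
        assert not filecmp.cmp(a["vcf_FAM1"], b["vcf_FAM1"], shallow=False)

    def test_no_background_leaves_only_planted_gene(self):
        cfg = SimulationConfig(seed=4, n_background_variants=0)
        cohort = simulate_family_cohort(cfg)
        for fam, variants in cohort.variants_by_family.items():
            assert [v.gene for v in variants] == [cfg.planted.gene]

    def test_study_shaped_defaults(self):
        cfg = SimulationConfig()
        assert cfg.n_families == 3
        assert cfg.n_affected == 2 and cfg.n_unaffected == 2
        assert cfg.n_cases == 112 and cfg.n_controls == 61

    def test_background_segregation_rate_matches_closed_form(self):
        """Background genotypes are Hardy-Weinberg draws independent of
        affection status, so a variant with population frequency p shows the
        dominant pattern with probability (2p(1-p))^2 * (1-p)^4."""
        cfg = SimulationConfig(
            seed=21, n_families=1, n_background_variants=12_000, planted=None
        )
        cohort = simulate_family_cohort(cfg)
        fam = "FAM1"
        keys = [v.key for v in cohort.variants_by_family[fam]]
        seg = apply_segregation(keys, cohort.genotypes_by_family[fam], cohort.pedigree)
        observed = len(seg[fam])
        probs = np.array([
            (2 * p * (1 - p)) ** 2 * (1 - p) ** 4
            for p in (cohort.population_af[fam][k] for k in keys)
        ])
        expected = probs.sum()
        sd = float(np.sqrt((probs * (1 - probs)).sum()))
        assert abs(observed - expected) <= 5 * max(sd, 1.0)


class TestCaseControl:
    def test_counts_sum_to_group_sizes(self):
        cfg = SimulationConfig(seed=5)
        for cc in simulate_case_control_counts(cfg):
            assert cc.n_cases == cfg.n_cases
            assert cc.n_controls == cfg.n_controls

    def test_null_allelic_or_is_one_on_average(self):
        """With equal case/control allele frequencies the mean log odds ratio
        over replicates is zero within Monte-Carlo error (~4 SEM)."""
        snps = (CaseControlSNP("null", case_af=0.1, control_af=0.1),)
        log_ors = []
        for seed in range(200):
            cfg = SimulationConfig(
                seed=seed, case_control_snps=snps, n_cases=500, n_controls=500
            )
            (cc,) = simulate_case_control_counts(cfg)
            res = odds_ratio_ci(
                (
                    2 * cc.case[2] + cc.case[1],
                    2 * cc.case[0] + cc.case[1],
                    2 * cc.control[2] + cc.control[1],
                    2 * cc.control[0] + cc.control[1],
                )
            )
            log_ors.append(np.log(res.odds_ratio))
        mean = float(np.mean(log_ors))
        sem = float(np.std(log_ors) / np.sqrt(len(log_ors)))
        assert abs(mean) <= 4 * sem + 0.01

    def test_effect_size_recovered_at_large_n(self):
        """case af 0.2 vs control 0.1: allelic OR should estimate
        (0.2/0.8)/(0.1/0.9) = 2.25 within 10% at n=10,000 per group."""
        snps = (CaseControlSNP("eff", case_af=0.2, control_af=0.1),)
        ors = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                seed=seed, case_control_snps=snps, n_cases=10_000, n_controls=10_000
            )
            (cc,) = simulate_case_control_counts(cfg)
            res = odds_ratio_ci(
                (
                    2 * cc.case[2] + cc.case[1],
                    2 * cc.case[0] + cc.case[1],
                    2 * cc.control[2] + cc.control[1],
                    2 * cc.control[0] + cc.control[1],
                )
            )
            ors.append(res.odds_ratio)
        target = (0.2 / 0.8) / (0.1 / 0.9)
        for or_ in ors:
            assert abs(or_ - target) / target <= 0.10

    def test_hwe_holds_in_generated_genotypes(self):
        """The generator draws genotypes under Hardy-Weinberg proportions, so
        the exact test should reject at no more than the nominal rate (it is
        conservative for discrete data); tolerance: rate in [0, 0.08] at
        alpha = 0.05 over 300 replicates."""
        snps = (CaseControlSNP("hwe", case_af=0.3, control_af=0.3),)
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            cfg = SimulationConfig(seed=seed, case_control_snps=snps)
            (cc,) = simulate_case_control_counts(cfg)
            if hwe_exact_check(cc.case) < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.08

    def test_zero_frequency_gives_all_hom_ref(self):
        snps = (CaseControlSNP("mono", case_af=0.0, control_af=0.0),)
        cfg = SimulationConfig(seed=3, case_control_snps=snps)
        (cc,) = simulate_case_control_counts(cfg)
        assert cc.case == (cfg.n_cases, 0, 0)
        assert cc.control == (cfg.n_controls, 0, 0)
        from famseq.exceptions import UndefinedOddsRatioError

        with pytest.raises(UndefinedOddsRatioError):
            odds_ratio_ci((0, 2 * cfg.n_cases, 0, 2 * cfg.n_controls), correction="none")


class TestConfigValidation:
    def test_effect_probs_must_sum_to_one(self):
        from famseq.variants import Effect

        with pytest.raises(ConfigError, match="sum"):
            SimulationConfig(effect_probs={Effect.INTRON: 0.5})

    def test_frequencies_must_be_probabilities(self):
        with pytest.raises(ConfigError):
            CaseControlSNP("bad", case_af=1.2, control_af=0.1)
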