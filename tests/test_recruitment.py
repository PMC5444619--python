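"""Adhesion dose-response rules, probability assembly and sampling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atherosim import params
from atherosim.recruitment import (ADHESION_RULES, LEUKOCYTE_TYPES,
                                   RecruitmentConfig, WSS_DOMAIN_UPPER,
                                   adhesion_probability, combine_and_sample,
                                   combined_probability, eval_rule,
                                   expected_tem, tem_fraction)


class TestRuleGoldenValues:
    def test_neutrophil_wss_polynomial(self):
        """1300 (0.26 x^2 - 0.8 x + 0.63) at 0.5 Pa = 383.5; zero beyond
        the 1.2 Pa cut-off."""
        rule = ADHESION_RULES[("NEUTROPHIL", "WSS")]
        assert eval_rule(rule, 0.5) == pytest.approx(383.5)
        assert eval_rule(rule, 2.0) == 0.0
        assert eval_rule(rule, 1.2) == 0.0      # open domain edge

    def test_tnfa_linear_branch(self):
        """1180 * 0.0996 x at x = 0.5 U/ml = 58.764."""
        rule = ADHESION_RULES[("NEUTROPHIL", "TNFA")]
        assert eval_rule(rule, 0.5) == pytest.approx(1180 * 0.0996 * 0.5)

    def test_tnfa_log_branch(self):
        rule = ADHESION_RULES[("MONOCYTE", "TNFA")]
        x = 10.0
        expect = 1180 * (0.80 - 0.68 * (1 - np.exp(-0.33 * np.log10(x) - 0.56)))
        assert eval_rule(rule, x) == pytest.approx(expect)

    def test_monocyte_wss_cubic(self):
        rule = ADHESION_RULES[("MONOCYTE", "WSS")]
        x = 0.5
        expect = 1600 * (-0.3295 * x ** 3 + 1.4 * x ** 2 - 1.8 * x + 0.79)
        assert eval_rule(rule, x) == pytest.approx(expect)

    def test_lymphocyte_wss_window(self):
        """The lymphocyte WSS pathway is open only on (0.04, 0.41) Pa."""
        rule = ADHESION_RULES[("LYMPHOCYTE", "WSS")]
        assert eval_rule(rule, 0.2) > 0
        assert eval_rule(rule, 0.03) == 0.0
        assert eval_rule(rule, 0.45) == 0.0

    def test_il1b_sigmoids(self):
        x = 0.5
        f_n = eval_rule(ADHESION_RULES[("NEUTROPHIL", "IL1B")], x)
        expect = 1900 * (0.10 + 0.19 * (1 - np.exp(-28.29 * x ** 1.46)))
        assert f_n == pytest.approx(expect)
        f_m = eval_rule(ADHESION_RULES[("MONOCYTE", "IL1B")], x)
        expect_m = 1600 * (0.14 + 0.80 * (1 - np.exp(-0.58 * x ** 1.19)))
        assert f_m == pytest.approx(expect_m)

    def test_cytokine_rules_silent_below_activation_floor(self):
        """Zero (or trace) cytokine concentration is no stimulus, despite
        the nonzero sigmoid intercepts."""
        floor = params.CYTOKINE_ACTIVATION_THRESHOLD_U_ML
        for t in LEUKOCYTE_TYPES:
            for s in ("TNFA", "IL1B"):
                rule = ADHESION_RULES[(t, s)]
                assert eval_rule(rule, 0.0) == 0.0
                assert eval_rule(rule, floor / 10) == 0.0
                assert eval_rule(rule, max(floor, 1e-3)) >= 0.0

    def test_negative_stimulus_rejected(self):
        with pytest.raises(ValueError):
            eval_rule(ADHESION_RULES[("NEUTROPHIL", "WSS")], -0.1)


class TestHealthyHomeostasis:
    def test_all_wss_pathways_silent_at_healthy_shear(self):
        """At the healthy 1.4 Pa every WSS pathway is silent, and the
        cut-offs are ordered lymphocyte < monocyte < neutrophil."""
        for t in LEUKOCYTE_TYPES:
            assert eval_rule(ADHESION_RULES[(t, "WSS")], 1.4) == 0.0
        assert WSS_DOMAIN_UPPER["LYMPHOCYTE"] < WSS_DOMAIN_UPPER["MONOCYTE"] \
            < WSS_DOMAIN_UPPER["NEUTROPHIL"]

    def test_zero_probability_iff_zero_stimulus(self):
        cfg = RecruitmentConfig(kappa=1e-4)
        for t in LEUKOCYTE_TYPES:
            p = combined_probability(1.4, 0.0, 0.0, cfg, t)
            assert np.all(p == 0.0)
            p = combined_probability(0.5, 0.0, 0.0, cfg, t)
            if t != "LYMPHOCYTE":      # 0.5 Pa is outside the lymphocyte window
                assert np.all(p > 0.0)


class TestProbability:
    def test_zero_f_zero_p(self):
        cfg = RecruitmentConfig()
        assert adhesion_probability(0.0, cfg) == 0.0

    def test_monotone_in_f_and_linear_in_kappa(self):
        cfg = RecruitmentConfig(kappa=1e-6)
        grid = np.linspace(0, 500, 101)
        p = adhesion_probability(grid, cfg)
        assert np.all(np.diff(p) >= 0)
        cfg2 = dataclasses.replace(cfg, kappa=2e-6)
        below_clamp = adhesion_probability(grid, cfg)
        assert np.allclose(adhesion_probability(grid, cfg2), 2 * below_clamp)

    def test_clamped_to_unit_interval(self):
        cfg = RecruitmentConfig(kappa=1e3)
        assert adhesion_probability(1e6, cfg) == 1.0

    def test_expected_available_leukocytes(self):
        """Blood at 7000/mm^3, 62 % neutrophils, patch volume 0.001 mm^3
        gives 4.34 expected neutrophils per luminal patch."""
        cfg = RecruitmentConfig()
        assert cfg.expected_available("NEUTROPHIL") == pytest.approx(4.34)
        assert cfg.expected_available("MONOCYTE") == pytest.approx(0.371)
        assert cfg.expected_available("LYMPHOCYTE") == pytest.approx(2.1)


class TestTemFraction:
    def test_monocyte_at_normal_stiffness(self):
        """0.78*9 + 4.8*3 + 51.06 = 72.48 % at the normal 3 kPa."""
        assert tem_fraction(3.0, "MONOCYTE") == pytest.approx(72.48)
        assert tem_fraction(3.0, "LYMPHOCYTE") == pytest.approx(72.48)

    def test_neutrophil_line(self):
        assert tem_fraction(3.0, "NEUTROPHIL") == pytest.approx(9.18 * 3 + 46.96)

    def test_plateaus_above_5kpa(self):
        assert tem_fraction(6.0, "MONOCYTE") == 95.0
        assert tem_fraction(6.0, "NEUTROPHIL") == 91.0

    def test_below_domain_uses_lower_edge(self):
        assert tem_fraction(0.5, "MONOCYTE") == pytest.approx(
            0.78 + 4.8 + 51.06)
        assert tem_fraction(0.1, "NEUTROPHIL") == pytest.approx(
            9.18 * 0.42 + 46.96)
        with pytest.raises(ValueError):
            tem_fraction(0.0, "MONOCYTE")


class TestSampling:
    def test_all_zero_probability_no_adhesion(self, rng):
        cfg = RecruitmentConfig(kappa=1e-5)
        out = combine_and_sample(np.full(50, 1.4), 0.0, 0.0, cfg, rng)
        for adherent, migrated in out.values():
            assert adherent.sum() == 0
            assert migrated.sum() == 0

    def test_sampling_mean_matches_expectation(self, rng):
        """Monte-Carlo mean of sampled TEM equals N * p * %TEM/100."""
        cfg = RecruitmentConfig(kappa=3e-5)
        wss = np.full(2000, 0.5)
        expect = expected_tem(wss, 0.0, 0.0, cfg)
        draws = [sum(mig.sum() for _, mig in
                     combine_and_sample(wss, 0.0, 0.0, cfg, rng).values())
                 for _ in range(50)]
        mean = np.mean(draws)
        sd = np.std(draws) / np.sqrt(len(draws))
        assert abs(mean - expect) < max(5 * sd, 0.05 * expect)

    def test_tem_never_exceeds_adherent(self, rng):
        cfg = RecruitmentConfig(kappa=1e-3)
        out = combine_and_sample(np.full(300, 0.3), 0.05, 0.02, cfg, rng)
        for adherent, migrated in out.values():
            assert np.all(migrated <= adherent)

    def test_independent_or_vs_additive(self):
        cfg_or = RecruitmentConfig(kappa=1e-4)
        cfg_add = RecruitmentConfig(kappa=1e-4, combination="additive")
        p_or = combined_probability(0.5, 5.0, 1.0, cfg_or, "NEUTROPHIL")
        p_add = combined_probability(0.5, 5.0, 1.0, cfg_add, "NEUTROPHIL")
        assert p_or <= p_add + 1e-12
        assert p_or > max(
            combined_probability(0.5, 0.0, 0.0, cfg_or, "NEUTROPHIL") - 1e-12,
            0.0)


@settings(max_examples=50, deadline=None)
@given(x=st.floats(0.0, 10.0),
       t=st.sampled_from(LEUKOCYTE_TYPES),
       s=st.sampled_from(("WSS", "TNFA", "IL1B")))
def test_rules_nonnegative_everywhere(x, t, s):
    assert eval_rule(ADHESION_RULES[(t, s)], x) >= 0.0
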