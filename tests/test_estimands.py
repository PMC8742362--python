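"""Ground-truth estimands: null invariance, closed forms, oracle agreement,
and the structural side-condition checks."""

import pytest

from casecausal import (
    DGPSpec,
    check_constant_hazards,
    check_effect_homogeneity,
    preset_dgp,
    true_conditional_odds_ratio,
    true_hazard_ratio,
    true_marginal_odds_ratio,
    true_marginal_risk_ratio,
    validate_spec,
)
from casecausal.errors import UndefinedEstimandError

from oracles import gformula_hazards, gformula_risk


class TestNullInvariance:
    def test_all_estimands_equal_one_without_exposure_pathway(self, presets):
        spec = presets["null"]
        assert true_marginal_risk_ratio(spec).value == pytest.approx(1, abs=1e-10)
        for v in true_conditional_odds_ratio(spec).value.values():
            assert v == pytest.approx(1, abs=1e-10)
        for pair in ("baseline", "sustained"):
            for v in true_hazard_ratio(spec, pair, "marginal").value.values():
                assert v == pytest.approx(1, abs=1e-10)
        for v in true_hazard_ratio(spec, "sustained", "history").value.values():
            if v is not None:
                assert v == pytest.approx(1, abs=1e-10)


class TestClosedFormsAndOracles:
    def test_single_window_proportional_hazard_gives_rr_equal_c(self):
        c = 1.7
        spec = validate_spec(
            DGPSpec(
                K=1, covariate_space=(0, 1),
                init_l=lambda u: {0: 0.5, 1: 0.5},
                exposure_law=lambda k, u, l, a: 0.3 + 0.2 * l[0],
                hazard_law=lambda k, u, l, a: (0.05 + 0.05 * l[0]) * c ** a[0],
            )
        )
        assert true_marginal_risk_ratio(spec).value == pytest.approx(c, abs=1e-10)

    @pytest.mark.parametrize("name", ["confounded-binary", "unmeasured-U",
                                      "tv-confounding"])
    def test_marginal_rr_matches_gformula(self, presets, name):
        spec = presets[name]
        oracle = gformula_risk(spec, "baseline", 1) / gformula_risk(
            spec, "baseline", 0
        )
        assert true_marginal_risk_ratio(spec).value == pytest.approx(
            oracle, abs=1e-12
        )

    def test_conditional_or_matches_gformula_per_stratum(self, presets):
        spec = presets["confounded-binary"]
        got = true_conditional_odds_ratio(spec).value
        for l in (0, 1):
            r1 = gformula_risk(spec, "baseline", 1, condition_l0=l)
            r0 = gformula_risk(spec, "baseline", 0, condition_l0=l)
            oracle = (r1 / (1 - r1)) / (r0 / (1 - r0))
            assert got[l] == pytest.approx(oracle, abs=1e-12)

    def test_homogeneous_or_preset_constant_across_strata(self, presets):
        got = true_conditional_odds_ratio(presets["confounded-homogeneous-or"])
        vals = list(got.value.values())
        assert vals[0] == pytest.approx(vals[1], abs=1e-10)

    def test_sustained_hazards_match_gformula_under_tv_confounding(self, presets):
        spec = presets["tv-confounding"]
        got = true_hazard_ratio(spec, "sustained", "marginal").value
        h1 = gformula_hazards(spec, "sustained", 1)
        h0 = gformula_hazards(spec, "sustained", 0)
        for k in range(spec.K):
            assert got[k] == pytest.approx(h1[k] / h0[k], abs=1e-12)

    def test_zero_denominator_raises(self):
        spec = validate_spec(
            DGPSpec(
                K=1, covariate_space=(0,),
                init_l=lambda u: {0: 1.0},
                exposure_law=lambda k, u, l, a: 0.5,
                hazard_law=lambda k, u, l, a: 0.3 * a[0],  # no risk when A=0
            )
        )
        with pytest.raises(UndefinedEstimandError):
            true_marginal_risk_ratio(spec)


class TestConstantHazardCheck:
    def test_enforced_preset_holds(self, presets):
        rep = check_constant_hazards(presets["constant-hazard"], "baseline")
        assert rep["holds"] and rep["max_abs_deviation"] < 1e-10
        rep = check_constant_hazards(presets["tv-confounding"], "sustained")
        assert rep["holds"] and rep["max_abs_deviation"] < 1e-10

    def test_nonconstant_preset_fails_with_enumerated_deviation(self, presets):
        spec = presets["nonconstant-hazard"]
        rep = check_constant_hazards(spec, "baseline")
        assert not rep["holds"]
        h1 = gformula_hazards(spec, "baseline", 1)
        h0 = gformula_hazards(spec, "baseline", 0)
        expect = max(
            max(h) - min(h) for h in (h1, h0)
        )
        assert rep["max_abs_deviation"] == pytest.approx(expect, abs=1e-12)

    def test_single_window_holds_vacuously(self):
        spec = validate_spec(
            DGPSpec(
                K=1, covariate_space=(0, 1),
                init_l=lambda u: {0: 0.5, 1: 0.5},
                exposure_law=lambda k, u, l, a: 0.5,
                hazard_law=lambda k, u, l, a: 0.1 + 0.2 * a[0],
            )
        )
        assert check_constant_hazards(spec, "baseline")["holds"]


class TestEffectHomogeneity:
    def test_enforced_presets_hold(self, presets):
        assert check_effect_homogeneity(
            presets["confounded-homogeneous-rr"], "risk-ratio"
        )["holds"]
        assert check_effect_homogeneity(
            presets["confounded-homogeneous-or"], "odds-ratio"
        )["holds"]
        assert check_effect_homogeneity(
            presets["prop-hazard"], "hazard-ratio", mode="ITT"
        )["holds"]
        assert check_effect_homogeneity(
            presets["tv-confounding-prop"], "hazard-ratio", mode="PP"
        )["holds"]

    def test_interaction_preset_fails(self, presets):
        rep = check_effect_homogeneity(
            presets["confounded-binary"], "risk-ratio"
        )
        assert not rep["holds"] and rep["max_abs_deviation"] > 0.01

    def test_single_stratum_vacuous(self):
        spec = validate_spec(
            DGPSpec(
                K=2, covariate_space=(0,),
                init_l=lambda u: {0: 1.0},
                exposure_law=lambda k, u, l, a: 0.5,
                hazard_law=lambda k, u, l, a: 0.05 + 0.1 * a[-1],
            )
        )
        rep = check_effect_homogeneity(spec, "risk-ratio")
        assert rep["holds"] and rep["vacuous"]


class TestRareOutcomeLimit:
    def test_marginal_or_approaches_marginal_rr(self):
        """At overall risk <= 0.001 the marginal odds ratio sits within 2% of
        the marginal risk ratio, and the gap shrinks with the risk scale."""
        gaps = []
        for eps in (1e-3, 1e-4):
            spec = preset_dgp("rare-outcome", eps=eps)
            rr = true_marginal_risk_ratio(spec).value
            or_ = true_marginal_odds_ratio(spec).value
            gaps.append(abs(or_ / rr - 1.0))
        assert gaps[1] < gaps[0]
        assert gaps[1] < 0.02

    def test_marginal_or_flagged_as_not_survivor_identified(self, presets):
        res = true_marginal_odds_ratio(presets["confounded-binary"])
        assert res.meta["identified_by_survivor_sampling"] is False
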