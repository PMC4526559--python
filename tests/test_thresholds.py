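"""Closed-form thresholds: frozen examples and structural properties."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpmdx import (
    CognitiveWeight,
    DomainError,
    Scenario,
    TestProfile,
    TreatmentProfile,
    classify_regime,
    derive_gamma,
    dpm_testing_threshold,
    dpm_threshold,
    dpm_treatment_threshold,
    eut_test_thresholds,
    eut_threshold,
    percent,
    regret_threshold,
    threshold_set,
)
from dpmdx.thresholds import (
    dpm_testing_threshold_raw,
    dpm_threshold_raw,
    dpm_treatment_threshold_raw,
)


def _with_gamma(s, gamma):
    return dataclasses.replace(s, weight=CognitiveWeight(gamma=gamma))


@pytest.mark.parametrize("benefit, harm, expected", [
    (0.10, 0.37, 0.78723404),   # hand: 0.37/0.47
    (0.10, 0.004, 0.03846154),  # hand: 0.004/0.104
    (0.25, 0.25, 0.5),          # symmetric benefit/harm
])
def test_eut_threshold_examples(benefit, harm, expected):
    assert eut_threshold(benefit, harm) == pytest.approx(expected, abs=5e-9)


def test_eut_threshold_requires_positive_harm():
    with pytest.raises(DomainError):
        eut_threshold(0.1, 0.0)


@pytest.mark.parametrize("omission, commission, expected", [
    (0.2, 0.8, 0.8),
    (0.3, 0.3, 0.5),
    (0.0, 0.5, 1.0),  # zero intuited benefit: never treat spontaneously
])
def test_regret_threshold_examples(omission, commission, expected):
    assert regret_threshold(omission, commission) == pytest.approx(expected)


@pytest.mark.parametrize("pt_eut, pt_rg, expected", [
    (0.37 / 0.47, 1 / (1 + 1 / 8), 0.12912913),  # hand evaluation
    (0.5, 0.5, 0.0),                            # identical thresholds
    (0.03846154, 0.8, 1.0),                     # relative distance 19.8 -> 1
])
def test_derive_gamma_examples(pt_eut, pt_rg, expected):
    w = derive_gamma(pt_eut, pt_rg)
    assert w.gamma == pytest.approx(expected, abs=5e-8)
    assert w.mode == "derived"


def test_derive_gamma_rejects_zero_threshold():
    with pytest.raises(DomainError):
        derive_gamma(0.0, 0.5)


class TestDpmThresholdNoTest:
    """The two-strategy (treat vs. no-treat) dual-process threshold."""

    def test_hand_example(self):
        t = TreatmentProfile(benefit=0.10, harm=0.004,
                             regret_omission=0.3, regret_commission=0.6)
        # 0.0384615 * (1 + 0.125 * 75) = 0.3990
        assert dpm_threshold(t, CognitiveWeight(0.2)) == pytest.approx(
            0.39903846, abs=5e-9)

    def test_gamma_zero_returns_eut_even_without_regrets(self):
        t = TreatmentProfile(benefit=0.10, harm=0.004)
        assert dpm_threshold(t, CognitiveWeight(0.0)) == pytest.approx(
            eut_threshold(0.10, 0.004))

    def test_negative_raw_value_clamped_to_zero(self):
        t = TreatmentProfile(benefit=0.1, harm=0.1,
                             regret_omission=0.9, regret_commission=0.1)
        w = CognitiveWeight(0.5)
        assert dpm_threshold_raw(t, w) == pytest.approx(-1.5, abs=1e-12)
        assert dpm_threshold(t, w) == 0.0

    def test_gamma_one_raises(self):
        t = TreatmentProfile(benefit=0.1, harm=0.1,
                             regret_omission=0.9, regret_commission=0.1)
        with pytest.raises(DomainError, match="gamma"):
            dpm_threshold(t, CognitiveWeight(1.0))

    def test_missing_regrets_raise_when_gamma_positive(self):
        t = TreatmentProfile(benefit=0.1, harm=0.1)
        with pytest.raises(DomainError, match="regret"):
            dpm_threshold(t, CognitiveWeight(0.5))


class TestEutTestThresholds:
    """gamma = 0 testing/treatment thresholds of the three-strategy
    problem, with and without the objective test harm."""

    def test_mortality_case_study(self, presets):
        s = presets["mortality"]
        ptt, prx = eut_test_thresholds(s.treatment, s.test)
        assert ptt == pytest.approx(0.00278293, abs=5e-9)
        assert prx == pytest.approx(0.21171171, abs=5e-9)
        assert (percent(ptt), percent(prx)) == (0, 21)

    def test_erectile_dysfunction_case_study(self, presets):
        s = presets["erectile-dysfunction"]
        ptt, _ = eut_test_thresholds(s.treatment, s.test)
        assert ptt == pytest.approx(0.20517560, abs=5e-9)
        assert percent(ptt) == 21

    def test_zero_test_harm_makes_conventions_agree(self, presets):
        s = presets["mortality"]
        test = dataclasses.replace(s.test, harm=0.0)
        assert eut_test_thresholds(s.treatment, test) == \
            eut_test_thresholds(s.treatment, test, include_test_harm=True)

    def test_perfect_specificity_raises(self):
        t = TreatmentProfile(benefit=0.1, harm=0.004)
        with pytest.raises(DomainError, match="[Ss]pecificity"):
            eut_test_thresholds(t, TestProfile(sensitivity=0.86,
                                               specificity=1.0))

    @given(benefit=st.floats(0.0, 1.0), harm=st.floats(0.01, 1.0),
           sens=st.floats(0.5, 0.999), spec=st.floats(0.5, 0.999))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_window_well_ordered_without_test_harm(self, benefit, harm,
                                                   sens, spec):
        """Excluding test harms, the testing threshold never exceeds the
        treatment threshold (the EUT window cannot invert)."""
        t = TreatmentProfile(benefit=benefit, harm=harm)
        ptt, prx = eut_test_thresholds(
            t, TestProfile(sensitivity=sens, specificity=spec))
        assert 0.0 <= ptt <= prx <= 1.0


# the worked example shared by the Eq-2/Eq-3 tests below
_EX = Scenario(
    treatment=TreatmentProfile(benefit=0.10, harm=0.37,
                               regret_omission=0.2, regret_commission=0.4),
    test=TestProfile(sensitivity=0.86, specificity=0.94,
                     harm=0.0009, regret=0.1),
    weight=CognitiveWeight(0.3),
)


class TestDpmTestThresholds:
    def test_testing_threshold_hand_example(self):
        # 0.205176 * 1.010848
        assert dpm_testing_threshold(_EX) == pytest.approx(
            0.20740121, abs=5e-8)

    def test_treatment_threshold_hand_example(self):
        # 0.961305 * 0.945700
        assert dpm_treatment_threshold(_EX) == pytest.approx(
            0.90910644, abs=5e-8)

    def test_gamma_zero_reduces_to_eut(self):
        s = _with_gamma(_EX, 0.0)
        ptt_eut, prx_eut = eut_test_thresholds(s.treatment, s.test)
        assert dpm_testing_threshold(s) == ptt_eut
        assert dpm_treatment_threshold(s) == prx_eut

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9])
    def test_balanced_regrets_and_harmless_test_are_neutral(self, gamma):
        t = TreatmentProfile(benefit=0.10, harm=0.37,
                             regret_omission=0.4, regret_commission=0.4)
        te = TestProfile(sensitivity=0.86, specificity=0.94,
                         harm=0.0009, regret=0.0)
        s = Scenario(treatment=t, test=te, weight=CognitiveWeight(gamma))
        ptt_eut, prx_eut = eut_test_thresholds(t, te)
        assert dpm_testing_threshold(s) == pytest.approx(ptt_eut, abs=1e-15)
        assert dpm_treatment_threshold(s) == pytest.approx(prx_eut, abs=1e-15)

    def test_deviation_from_eut_is_monotone_in_gamma(self):
        ptt_eut, prx_eut = eut_test_thresholds(_EX.treatment, _EX.test)
        gammas = [0.0, 0.2, 0.4, 0.6, 0.8, 0.95]
        dev_tt = [abs(dpm_testing_threshold_raw(_with_gamma(_EX, g)) - ptt_eut)
                  for g in gammas]
        dev_rx = [abs(dpm_treatment_threshold_raw(_with_gamma(_EX, g)) - prx_eut)
                  for g in gammas]
        assert dev_tt == sorted(dev_tt)
        assert dev_rx == sorted(dev_rx)

    def test_perfect_specificity_raises(self):
        s = dataclasses.replace(
            _EX, test=dataclasses.replace(_EX.test, specificity=1.0))
        with pytest.raises(DomainError, match="[Ss]pecificity"):
            dpm_testing_threshold(s)


class TestThresholdSet:
    def test_all_public_thresholds_clamped(self, random_scenarios):
        for s in random_scenarios[:300]:
            ts = threshold_set(s)
            for value in (ts.pt_eut, ts.pt_rg, ts.pt_dpm, ts.ptt_eut,
                          ts.prx_eut, ts.ptt_dpm, ts.prx_dpm):
                assert 0.0 <= value <= 1.0

    def test_raw_values_preserved(self):
        ts = threshold_set(_with_gamma(_EX, 0.9))
        assert ts.ptt_dpm == min(max(ts.raw_ptt_dpm, 0.0), 1.0)
        assert ts.prx_dpm == min(max(ts.raw_prx_dpm, 0.0), 1.0)

    def test_round_trip_via_dict(self):
        ts = threshold_set(_EX)
        assert type(ts).from_dict(ts.to_dict()) == ts


class TestClassifyRegime:
    def test_raised_testing_lowered_treatment(self):
        # H_I + 4 H_IT = 0.8 > B_I = 0.2 but H_I = 0.4 < 0.2 + 0.4
        r = classify_regime(_EX)
        assert r.testing == "raised"
        assert r.treatment == "lowered"

    def test_balanced_boundary_is_unchanged(self):
        s = dataclasses.replace(
            _EX,
            treatment=_EX.treatment.with_regrets(0.4, 0.4),
            test=dataclasses.replace(_EX.test, regret=0.0))
        r = classify_regime(s)
        assert r.testing == "unchanged"
        assert r.treatment == "unchanged"

    def test_strong_intuited_benefit_inverts_window(self):
        # low-harm treatment, intuited benefit far above harm, heavy
        # type-1 weighting: treating dominates testing at any p
        s = Scenario(
            treatment=TreatmentProfile(benefit=0.10, harm=0.004,
                                       regret_omission=0.9,
                                       regret_commission=0.1),
            test=TestProfile(sensitivity=0.86, specificity=0.94,
                             harm=0.0009, regret=0.0),
            weight=CognitiveWeight(0.9))
        r = classify_regime(s)
        assert r.inverted_window


@pytest.mark.parametrize("x, expected", [
    (0.20518, 21),   # rounds up past the half
    (0.00278, 0),
    (0.125, 13),     # exact half rounds away from zero
    (-0.125, -13),
    (0.96130, 96),
])
def test_percent_rounds_half_away_from_zero(x, expected):
    assert percent(x) == expected
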