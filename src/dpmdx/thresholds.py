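"""Closed-form decision thresholds.

The classic threshold framework (Pauker & Kassirer) says: treat when the
probability of disease exceeds a threshold at which expected benefit and
expected harm of treatment balance.  With a diagnostic test available the
single threshold splits into a *testing threshold* ``p_tt`` (below it, do
nothing) and a *treatment threshold* ``p_rx`` (above it, treat without
testing); testing is worthwhile in between.

The dual-process model multiplies each expected-utility (EUT) threshold
by a bracket that encodes the decision maker's intuitive (type-1,
regret-based) attitude, weighted by gamma:

    p_t  = p_t,EUT  * [1 + g2 * (H_I/H)(1 - B_I/H_I)]
    p_tt = p_tt,EUT * [1 + g4 * (1-Sp)(1 + H_T/((1-Sp) H))
                             * ((H_I/H)(1 - B_I/H_I) + 4 H_IT/H)]
    p_rx = p_rx,EUT * [1 + g4 * Sp (1 - H_T/(Sp H))
                             * ((H_I/H)(1 - B_I/H_I) - 4 H_IT/H)]

with g2 = gamma/(2(1-gamma)), g4 = gamma/(4(1-gamma)), H the type-2
treatment harm, H_T the type-2 test harm, B_I/H_I the regrets of
omission/commission and H_IT the type-1 test regret.  At gamma = 0 every
bracket is 1 and the EUT thresholds are recovered; at gamma = 1 the forms
are undefined and the pure type-1 rule applies (see
:mod:`dpmdx.decision_tree`).

Results are clamped to [0, 1]; pre-clamp values are kept because their
position relative to the EUT threshold classifies the decision regime
(whether intuition raises or lowers the bar for testing and treating).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from .core import (
    CognitiveWeight,
    DomainError,
    Scenario,
    TestProfile,
    ThresholdSet,
    TreatmentProfile,
    validate_scenario,
)

__all__ = [
    "eut_threshold",
    "regret_threshold",
    "derive_gamma",
    "dpm_threshold",
    "dpm_threshold_raw",
    "eut_test_thresholds",
    "dpm_testing_threshold",
    "dpm_testing_threshold_raw",
    "dpm_treatment_threshold",
    "dpm_treatment_threshold_raw",
    "threshold_set",
    "Regime",
    "classify_regime",
    "percent",
]


def _clamp01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def percent(x: float) -> int:
    """Probability -> whole percent, rounding half away from zero.

    This is the reporting convention for human-readable tables (e.g.
    0.20518 -> 21); full precision is preserved everywhere else.
    """
    scaled = x * 100.0
    return int(math.floor(scaled + 0.5)) if scaled >= 0 else int(math.ceil(scaled - 0.5))


def eut_threshold(benefit: float, harm: float) -> float:
    """Expected-utility treatment threshold ``1 / (1 + B/H)``.

    The probability of disease at which treating and not treating have
    equal expected utility: ``p * B = (1 - p) * H``.
    """
    if harm <= 0:
        raise DomainError(f"harm must be > 0, got {harm!r}")
    if benefit < 0:
        raise DomainError(f"benefit must be >= 0, got {benefit!r}")
    return harm / (benefit + harm)


def regret_threshold(regret_omission: float, regret_commission: float) -> float:
    """Regret-based treatment threshold ``1 / (1 + B_I/H_I)``.

    Same indifference construction as :func:`eut_threshold` but with the
    type-1 regrets of omission (benefit role) and commission (harm role).
    """
    if regret_commission <= 0:
        raise DomainError(
            f"regret_commission must be > 0, got {regret_commission!r}")
    if regret_omission < 0:
        raise DomainError(
            f"regret_omission must be >= 0, got {regret_omission!r}")
    return regret_commission / (regret_omission + regret_commission)


def derive_gamma(pt_eut: float, pt_rg: float) -> CognitiveWeight:
    """Cognitive weight from the two treatment thresholds.

    gamma = min(|p_t,EUT - p_t,RG| / p_t,EUT, 1): the relative distance
    between the analytic and the regret-based threshold, capped at 1.
    """
    if pt_eut <= 0:
        raise DomainError(
            f"EUT threshold must be > 0 to derive gamma, got {pt_eut!r}")
    g = min(abs(pt_eut - pt_rg) / pt_eut, 1.0)
    return CognitiveWeight(gamma=g, mode="derived")


def _type1_bracket_term(t: TreatmentProfile) -> float:
    """(H_I/H)(1 - B_I/H_I) = (H_I - B_I)/H — the signed intuitive
    tilt shared by all three brackets."""
    b1, h1 = t.require_type1()
    return (h1 - b1) / t.harm


def _gamma_odds(w: CognitiveWeight) -> float:
    if w.is_type1_only:
        raise DomainError(
            "closed-form thresholds are invalid at gamma = 1; use the "
            "pure type-1 decision rule (decision_tree module)")
    return w.gamma / (1.0 - w.gamma)


def dpm_threshold_raw(t: TreatmentProfile, w: CognitiveWeight) -> float:
    """Pre-clamp dual-process treatment threshold (no test available)."""
    p_eut = eut_threshold(t.benefit, t.harm)
    if w.gamma == 0.0:
        return p_eut
    bracket = 1.0 + _gamma_odds(w) / 2.0 * _type1_bracket_term(t)
    return p_eut * bracket


def dpm_threshold(t: TreatmentProfile, w: CognitiveWeight) -> float:
    """Dual-process treatment threshold (no test), clamped to [0, 1].

    Equals the EUT threshold when gamma = 0 or when the regrets balance
    (B_I = H_I).  A negative pre-clamp value means intuition favours
    treatment so strongly that treating is preferred at any probability;
    it is reported as 0.
    """
    return _clamp01(dpm_threshold_raw(t, w))


def eut_test_thresholds(t: TreatmentProfile, test: TestProfile, *,
                        include_test_harm: bool = False) -> Tuple[float, float]:
    """Expected-utility testing and treatment thresholds (gamma = 0 limit).

    p_tt,EUT = ((1-Sp) H + k H_T) / (S B + (1-Sp) H)
    p_rx,EUT = (Sp H - k H_T) / ((1-S) B + Sp H)

    where k = 1 if ``include_test_harm`` else 0.  With k = 1 these are the
    exact gamma = 0 indifference points of the decision-tree valuations;
    with k = 0 (default) the objective test harm is excluded, the
    convention under which the published prostate case-study values are
    stated.  p_rx is floored at 0 and p_tt capped at 1 (reachable only
    when a very harmful test is included).
    """
    if not (0.0 < test.specificity < 1.0):
        raise DomainError(
            "EUT test thresholds are undefined at specificity of 0% or "
            f"100%, got {test.specificity!r}")
    s, sp, h, b = test.sensitivity, test.specificity, t.harm, t.benefit
    k = test.harm if include_test_harm else 0.0
    ptt = ((1.0 - sp) * h + k) / (s * b + (1.0 - sp) * h)
    prx = (sp * h - k) / ((1.0 - s) * b + sp * h)
    return min(ptt, 1.0), max(prx, 0.0)


def dpm_testing_threshold_raw(s: Scenario, *,
                              include_test_harm: bool = False) -> float:
    """Pre-clamp dual-process testing threshold."""
    validate_scenario(s, for_test_thresholds=True)
    ptt_eut, _ = eut_test_thresholds(s.treatment, s.test,
                                     include_test_harm=include_test_harm)
    if s.weight.gamma == 0.0:
        return ptt_eut
    t, test = s.treatment, s.test
    sp = test.specificity
    g4 = _gamma_odds(s.weight) / 4.0
    harm_factor = (1.0 - sp) * (1.0 + test.harm / ((1.0 - sp) * t.harm))
    tilt = _type1_bracket_term(t) + 4.0 * test.regret / t.harm
    return ptt_eut * (1.0 + g4 * harm_factor * tilt)


def dpm_testing_threshold(s: Scenario, *,
                          include_test_harm: bool = False) -> float:
    """Dual-process testing threshold, clamped to [0, 1].

    Below it the decision maker prefers doing nothing to ordering the
    test.  Raised above the EUT value exactly when
    ``H_I + 4 H_IT > B_I`` (intuited harms of treatment and test outweigh
    intuited benefit), lowered when the inequality reverses; test
    accuracy does not change the direction.
    """
    return _clamp01(dpm_testing_threshold_raw(
        s, include_test_harm=include_test_harm))


def dpm_treatment_threshold_raw(s: Scenario, *,
                                include_test_harm: bool = False) -> float:
    """Pre-clamp dual-process treatment threshold (test available)."""
    validate_scenario(s, for_test_thresholds=True)
    _, prx_eut = eut_test_thresholds(s.treatment, s.test,
                                     include_test_harm=include_test_harm)
    if s.weight.gamma == 0.0:
        return prx_eut
    t, test = s.treatment, s.test
    sp = test.specificity
    g4 = _gamma_odds(s.weight) / 4.0
    harm_factor = sp * (1.0 - test.harm / (sp * t.harm))
    tilt = _type1_bracket_term(t) - 4.0 * test.regret / t.harm
    return prx_eut * (1.0 + g4 * harm_factor * tilt)


def dpm_treatment_threshold(s: Scenario, *,
                            include_test_harm: bool = False) -> float:
    """Dual-process treatment threshold, clamped to [0, 1].

    Above it, treat immediately rather than test first.  Raised above the
    EUT value exactly when ``H_I > B_I + 4 H_IT`` (assuming the test is
    objectively less harmful than the treatment, ``H_T < Sp * H``),
    lowered when reversed.
    """
    return _clamp01(dpm_treatment_threshold_raw(
        s, include_test_harm=include_test_harm))


def threshold_set(s: Scenario, *, include_test_harm: bool = False) -> ThresholdSet:
    """Compute every threshold of a scenario in one pass."""
    t = s.treatment
    pt_eut = eut_threshold(t.benefit, t.harm)
    pt_rg = (regret_threshold(*t.require_type1())
             if t.has_type1 else None)
    raw_pt = dpm_threshold_raw(t, s.weight)
    ptt_eut, prx_eut = eut_test_thresholds(
        t, s.test, include_test_harm=include_test_harm)
    raw_ptt = dpm_testing_threshold_raw(s, include_test_harm=include_test_harm)
    raw_prx = dpm_treatment_threshold_raw(s, include_test_harm=include_test_harm)
    return ThresholdSet(
        pt_eut=pt_eut, pt_rg=pt_rg, pt_dpm=_clamp01(raw_pt),
        ptt_eut=ptt_eut, prx_eut=prx_eut,
        ptt_dpm=_clamp01(raw_ptt), prx_dpm=_clamp01(raw_prx),
        raw_pt_dpm=raw_pt, raw_ptt_dpm=raw_ptt, raw_prx_dpm=raw_prx,
        include_test_harm=include_test_harm,
    )


@dataclass(frozen=True)
class Regime:
    """How intuition shifts the thresholds relative to pure EUT.

    ``testing`` / ``treatment`` are "raised", "lowered" or "unchanged";
    ``inverted_window`` flags the regime where the (pre-clamp) treatment
    threshold falls below the testing threshold, so no probability range
    favours testing — impossible under pure EUT but observed in practice.
    """

    testing: str
    treatment: str
    inverted_window: bool


def classify_regime(s: Scenario, *, include_test_harm: bool = False) -> Regime:
    """Classify the sign regime of a scenario.

    The directions follow the bracket signs: testing threshold raised iff
    ``H_I + 4 H_IT > B_I``; treatment threshold raised iff
    ``H_I > B_I + 4 H_IT`` (stated under ``H_T < Sp * H``).  Exact
    equality is labelled "unchanged".
    """
    validate_scenario(s, for_sign_rules=True)
    b1, h1 = s.treatment.require_type1()
    four_hit = 4.0 * s.test.regret

    def label(lhs: float, rhs: float) -> str:
        if lhs > rhs:
            return "raised"
        if lhs < rhs:
            return "lowered"
        return "unchanged"

    testing = label(h1 + four_hit, b1)
    treatment = label(h1, b1 + four_hit)
    raw_ptt = dpm_testing_threshold_raw(s, include_test_harm=include_test_harm)
    raw_prx = dpm_treatment_threshold_raw(s, include_test_harm=include_test_harm)
    return Regime(testing=testing, treatment=treatment,
                  inverted_window=raw_prx < raw_ptt)
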