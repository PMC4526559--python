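"""Decision-tree valuation of the three management strategies.

A patient has the disease with probability ``p``.  The decision maker
chooses among doing nothing (``NoRx``), ordering a diagnostic test and
acting on its result (``Test``), or treating immediately (``Rx``).  Each
strategy's valuation blends a type-1 (regret) component, weighted
``gamma``, with a type-2 expected-utility component, weighted
``1 - gamma``:

    V(Rx)   = g/2 (U1_2 - U1_4) + (1-g)[p U2_1 + (1-p) U2_2]
    V(NoRx) = g/2 (U1_3 - U1_1) + (1-g)[p U2_3 + (1-p) U2_4]
    V(T)    = g/4 (U1_2 - U1_4 + U1_3 - U1_1)
              + (1-g)[p S U2_1 + (1-p)(1-Sp) U2_2
                      + p (1-S) U2_3 + (1-p) Sp U2_4]
              - (g H_IT + (1-g) H_T)

(outcome indices: 1 treated/diseased, 2 treated/healthy, 3
untreated/diseased, 4 untreated/healthy; S/Sp sensitivity and
specificity, H_T / H_IT the type-2/type-1 test harms).  Every valuation
is affine in ``p``, so any pairwise indifference probability is the root
of a linear function — this module's numeric solver is the independent
oracle against which the closed-form thresholds are checked.

At gamma = 1 the probability weights drop out entirely: intuition treats
each choice as a yes/no outcome, the test can never have the highest
valuation (for any nonnegative test regret), and the decision reduces to
treating iff the regret of omission exceeds the regret of commission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

from scipy.optimize import brentq

from .core import (
    CognitiveWeight,
    DomainError,
    Scenario,
    TestProfile,
    UtilitySet,
    validate_scenario,
)
from . import thresholds as th

__all__ = [
    "Strategy",
    "BranchProbabilities",
    "ValuationTriple",
    "Action",
    "branch_probabilities",
    "valuations",
    "scenario_valuations",
    "solve_indifference",
    "recommend_by_threshold",
    "recommend_by_valuation",
]

logger = logging.getLogger(__name__)

_LINEAR_TOL = 1e-10


class Strategy(str, Enum):
    """The three management strategies."""

    NO_TREAT = "NoRx"
    TEST = "Test"
    TREAT = "Rx"


@dataclass(frozen=True)
class BranchProbabilities:
    """Probabilities of and within the positive/negative test branches.

    ``positive = p*S + (1-p)*(1-Sp)`` etc.; the within-branch entries are
    the posterior (Bayes) probabilities of disease given the result.
    """

    positive: float
    disease_given_positive: float
    no_disease_given_positive: float
    negative: float
    disease_given_negative: float
    no_disease_given_negative: float


@dataclass(frozen=True)
class ValuationTriple:
    """Expected valuations of the three strategies at a given ``p``."""

    treat: float
    no_treat: float
    test: float

    def of(self, strategy: Strategy) -> float:
        return {Strategy.TREAT: self.treat,
                Strategy.NO_TREAT: self.no_treat,
                Strategy.TEST: self.test}[strategy]


@dataclass(frozen=True)
class Action:
    """A recommended strategy plus how it was derived."""

    choice: Strategy
    provenance: str  # "threshold-rule" | "valuation-argmax" | "type1-only"


def branch_probabilities(p: float, test: TestProfile) -> BranchProbabilities:
    """Marginal and posterior probabilities of the test branches."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"disease probability must lie in [0, 1], got {p!r}")
    s, sp = test.sensitivity, test.specificity
    pos = p * s + (1.0 - p) * (1.0 - sp)
    neg = (1.0 - p) * sp + p * (1.0 - s)
    d_pos = p * s / pos if pos > 0 else 0.0
    d_neg = p * (1.0 - s) / neg if neg > 0 else 0.0
    return BranchProbabilities(
        positive=pos,
        disease_given_positive=d_pos,
        no_disease_given_positive=1.0 - d_pos if pos > 0 else 0.0,
        negative=neg,
        disease_given_negative=d_neg,
        no_disease_given_negative=1.0 - d_neg if neg > 0 else 0.0,
    )


def valuations(u: UtilitySet, test: TestProfile, weight: CognitiveWeight,
               p: float) -> ValuationTriple:
    """Expected valuations of treat / no-treat / test at probability ``p``.

    Valid for every gamma in [0, 1] (unlike the closed-form thresholds).
    """
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"disease probability must lie in [0, 1], got {p!r}")
    g = weight.gamma
    u1, u2 = u.type1, u.type2
    s, sp = test.sensitivity, test.specificity
    v_treat = g / 2.0 * (u1[1] - u1[3]) \
        + (1.0 - g) * (p * u2[0] + (1.0 - p) * u2[1])
    v_no_treat = g / 2.0 * (u1[2] - u1[0]) \
        + (1.0 - g) * (p * u2[2] + (1.0 - p) * u2[3])
    v_test = g / 4.0 * (u1[1] - u1[3] + u1[2] - u1[0]) \
        + (1.0 - g) * (p * s * u2[0]
                       + (1.0 - p) * (1.0 - sp) * u2[1]
                       + p * (1.0 - s) * u2[2]
                       + (1.0 - p) * sp * u2[3]) \
        - (g * test.regret + (1.0 - g) * test.harm)
    return ValuationTriple(treat=v_treat, no_treat=v_no_treat, test=v_test)


def scenario_valuations(s: Scenario, p: float) -> ValuationTriple:
    """Valuations from a scenario's profiles (anchored utilities).

    Unelicited type-1 regrets are tolerated only at gamma = 0, where
    their weight is exactly zero.
    """
    u = UtilitySet.from_treatment(
        s.treatment, missing_type1_ok=(s.weight.gamma == 0.0))
    return valuations(u, s.test, s.weight, p)


def solve_indifference(pair: Tuple[Strategy, Strategy],
                       s: Scenario) -> Optional[float]:
    """Probability at which the two strategies have equal valuation.

    Each valuation is affine in ``p``, so the difference has at most one
    root: solved exactly from the values at ``p = 0`` and ``p = 1``, with
    a bracketing (Brent) fall-back should the linearity assumption ever
    be violated by an extended valuation form.  Returns ``None`` when the
    difference is constant (degenerate slope) or the root lies outside
    [0, 1].
    """
    if s.weight.is_type1_only:
        raise DomainError(
            "indifference probabilities are undefined at gamma = 1: "
            "valuations no longer depend on p")
    a, b = pair

    def diff(p: float) -> float:
        v = scenario_valuations(s, p)
        return v.of(a) - v.of(b)

    f0, f1 = diff(0.0), diff(1.0)
    slope = f1 - f0
    if abs(slope) < _LINEAR_TOL:
        logger.info("degenerate indifference problem for %s vs %s: "
                    "valuation difference is constant (%.3g)", a.value,
                    b.value, f0)
        return None
    root = -f0 / slope
    if not (0.0 <= root <= 1.0):
        return None
    if abs(diff(root)) > _LINEAR_TOL and f0 * f1 < 0:
        root = brentq(diff, 0.0, 1.0, xtol=_LINEAR_TOL)
    return root


def _type1_only_action(s: Scenario) -> Action:
    """gamma = 1 rule: treat iff intuited benefit exceeds intuited harm.

    Testing is never chosen — V(T) is dominated by the better of the
    other two whenever the test regret is nonnegative.  The tie
    (regrets exactly balanced) goes to the least interventional choice.
    """
    b1, h1 = s.treatment.require_type1()
    choice = Strategy.TREAT if b1 > h1 else Strategy.NO_TREAT
    return Action(choice=choice, provenance="type1-only")


def recommend_by_threshold(s: Scenario, p: float, *,
                           include_test_harm: bool = False) -> Action:
    """Recommend a strategy from the threshold windows.

    Standard rule: do nothing below the testing threshold, test between
    the two thresholds, treat at or above the treatment threshold.  When
    the window is inverted (treatment threshold at or below the testing
    threshold) testing is never indicated and the two-strategy treatment
    threshold decides treat vs. no-treat.  At gamma = 1 the closed forms
    are invalid and the pure type-1 rule is applied instead.
    """
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"disease probability must lie in [0, 1], got {p!r}")
    if s.weight.is_type1_only:
        logger.warning("gamma >= 1 - guard: routing to pure type-1 rule")
        return _type1_only_action(s)
    ptt = th.dpm_testing_threshold(s, include_test_harm=include_test_harm)
    prx = th.dpm_treatment_threshold(s, include_test_harm=include_test_harm)
    if prx > ptt:
        if p < ptt:
            choice = Strategy.NO_TREAT
        elif p < prx:
            choice = Strategy.TEST
        else:
            choice = Strategy.TREAT
    else:
        # inverted window: no probability range favours testing
        pt = th.dpm_threshold(s.treatment, s.weight)
        choice = Strategy.TREAT if p >= pt else Strategy.NO_TREAT
    return Action(choice=choice, provenance="threshold-rule")


def recommend_by_valuation(s: Scenario, p: float) -> Action:
    """Recommend the strategy with the highest expected valuation.

    Model-faithful alternative to the threshold rule (identical away
    from thresholds when the same test-harm convention is used); valid
    for every gamma including 1.  Ties go to the least interventional
    strategy (no-treat over test over treat).
    """
    v = scenario_valuations(validate_scenario(s), p)
    best = Strategy.NO_TREAT
    for cand in (Strategy.TEST, Strategy.TREAT):
        if v.of(cand) > v.of(best):
            best = cand
    return Action(choice=best, provenance="valuation-argmax")
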