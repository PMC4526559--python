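"""Domain types for dual-process clinical decision thresholds.

The model values a clinical action by combining two modes of cognition:

* **type 2 (analytic)** — expected-utility weighing of evidence-based
  benefit and harm of treatment, the classic threshold framework;
* **type 1 (intuitive)** — regret-based weighing, where regret of
  omission (failing to treat a diseased patient) plays the role of
  benefit and regret of commission (treating a healthy patient) the
  role of harm.

The blend is controlled by a cognitive weight ``gamma`` in [0, 1]:
``gamma = 0`` is pure expected-utility reasoning, ``gamma = 1`` pure
intuition.

All benefits, harms and regrets are dimensionless utilities on a common
[0, 1]-anchored scale.  Only *differences* of utilities enter any
threshold or valuation, so the absolute anchor is a free convention;
:meth:`UtilitySet.from_treatment` fixes one (untreated outcomes at zero)
and every indifference probability is invariant to shifting it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

__all__ = [
    "DomainError",
    "GAMMA_GUARD",
    "TreatmentProfile",
    "TestProfile",
    "CognitiveWeight",
    "UtilitySet",
    "Scenario",
    "ThresholdSet",
    "validate_scenario",
    "utilities_from_profiles",
]

#: Closed-form thresholds divide by (1 - gamma); weights closer to 1 than
#: this guard are routed to the pure type-1 special case instead.
GAMMA_GUARD = 1e-9


class DomainError(ValueError):
    """A parameter violates the model's domain restrictions."""


def _check_prob(name: str, value: float, *, lo_open: bool = False,
                hi_open: bool = False) -> None:
    if not (0.0 <= value <= 1.0):
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")
    if lo_open and value == 0.0:
        raise DomainError(f"{name} must be strictly positive")
    if hi_open and value == 1.0:
        raise DomainError(f"{name} must be strictly less than 1")


@dataclass(frozen=True)
class TreatmentProfile:
    """Benefit and harm of a treatment under both cognitive modes.

    Parameters
    ----------
    benefit
        Net type-2 (evidence-based) benefit B of treating a diseased
        patient, utility units; must be >= 0.
    harm
        Net type-2 harm H of treating a non-diseased patient; must be
        strictly positive (every real treatment carries some harm, and
        every threshold formula divides by it).
    regret_omission
        Type-1 "benefit": regret felt over withholding treatment from a
        diseased patient.  ``None`` until elicited from the decision
        maker.
    regret_commission
        Type-1 "harm": regret felt over treating a healthy patient.
        Strictly positive when supplied.
    """

    benefit: float
    harm: float
    regret_omission: Optional[float] = None
    regret_commission: Optional[float] = None

    def __post_init__(self) -> None:
        if self.benefit < 0:
            raise DomainError(
                f"treatment benefit (B) must be >= 0, got {self.benefit!r}")
        if self.harm <= 0:
            raise DomainError(
                f"treatment harm (H) must be > 0, got {self.harm!r}")
        if (self.regret_omission is None) != (self.regret_commission is None):
            raise DomainError(
                "regret_omission and regret_commission must be supplied "
                "together")
        if self.regret_omission is not None:
            if self.regret_omission < 0:
                raise DomainError(
                    "regret_omission (type-1 benefit) must be >= 0, "
                    f"got {self.regret_omission!r}")
            if self.regret_commission is not None and self.regret_commission <= 0:
                raise DomainError(
                    "regret_commission (type-1 harm) must be > 0, "
                    f"got {self.regret_commission!r}")

    @property
    def has_type1(self) -> bool:
        """Whether the type-1 regret pair has been elicited."""
        return self.regret_omission is not None

    def with_regrets(self, omission: float, commission: float) -> "TreatmentProfile":
        """Return a copy with the type-1 regret pair filled in."""
        return replace(self, regret_omission=omission,
                       regret_commission=commission)

    def require_type1(self) -> Tuple[float, float]:
        """Return (regret_omission, regret_commission), raising if unset."""
        if not self.has_type1:
            raise DomainError(
                "type-1 regrets (regret_omission, regret_commission) are "
                "required for this operation but have not been elicited")
        return self.regret_omission, self.regret_commission  # type: ignore[return-value]


@dataclass(frozen=True)
class TestProfile:
    """Accuracy and harms of a diagnostic test.

    ``harm`` is the type-2 (objective) harm of undergoing the test and
    ``regret`` the type-1 (felt) harm; both default to zero for an
    innocuous test.  Specificity may be 1.0 at construction, but the
    testing-threshold closed form is undefined there and will raise.
    """

    sensitivity: float
    specificity: float
    harm: float = 0.0
    regret: float = 0.0

    def __post_init__(self) -> None:
        _check_prob("sensitivity (S)", self.sensitivity, lo_open=True)
        _check_prob("specificity (Sp)", self.specificity, lo_open=True)
        if self.harm < 0:
            raise DomainError(
                f"test harm (H_T, type 2) must be >= 0, got {self.harm!r}")
        if self.regret < 0:
            raise DomainError(
                f"test regret (H_T, type 1) must be >= 0, got {self.regret!r}")


@dataclass(frozen=True)
class CognitiveWeight:
    """Weight gamma of type-1 (intuitive) processes in the decision.

    ``mode`` records whether the weight was supplied directly or derived
    from the relative distance between the expected-utility and
    regret-based treatment thresholds.
    """

    gamma: float
    mode: str = "direct"  # "direct" | "derived"

    def __post_init__(self) -> None:
        _check_prob("gamma", self.gamma)
        if self.mode not in ("direct", "derived"):
            raise DomainError(f"unknown CognitiveWeight mode {self.mode!r}")

    @property
    def is_type1_only(self) -> bool:
        """True when gamma is (numerically) 1: closed forms are invalid
        and the pure type-1 decision rule applies."""
        return self.gamma >= 1.0 - GAMMA_GUARD


@dataclass(frozen=True)
class UtilitySet:
    """Outcome utilities under both cognitive modes.

    Outcomes are indexed 1..4:

    1. treated, diseased
    2. treated, non-diseased
    3. untreated, diseased
    4. untreated, non-diseased

    stored here as 4-tuples (index 0 = outcome 1).  The anchoring used by
    :meth:`from_treatment` places both "correct inaction" outcomes at 0 so
    that the benefit/harm differences are recovered directly:
    ``B = U2[1] - U2[3]`` and ``H = U2[4] - U2[2]`` (same for type 1).
    """

    type1: Tuple[float, float, float, float]
    type2: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for label, vals in (("type1", self.type1), ("type2", self.type2)):
            if len(vals) != 4:
                raise DomainError(f"{label} utilities must have 4 entries")

    @classmethod
    def from_treatment(cls, t: TreatmentProfile, *,
                       missing_type1_ok: bool = False) -> "UtilitySet":
        """Anchor a utility set from a treatment profile.

        Convention: U(untreated, diseased) = U(treated, non-diseased) = 0,
        so U(treated, diseased) = benefit and U(untreated, non-diseased)
        = harm, in both modes.  Indifference probabilities are invariant
        to adding any constant to all eight utilities.

        With ``missing_type1_ok`` unelicited regrets become zeros; callers
        may only use that when the type-1 weight is exactly zero.
        """
        if t.has_type1:
            b1, h1 = t.regret_omission, t.regret_commission
        elif missing_type1_ok:
            b1, h1 = 0.0, 0.0
        else:
            t.require_type1()
        return cls(type1=(b1, 0.0, 0.0, h1),
                   type2=(t.benefit, 0.0, 0.0, t.harm))

    def shifted(self, c: float) -> "UtilitySet":
        """Add a constant to all eight utilities (affine re-anchoring)."""
        return UtilitySet(type1=tuple(u + c for u in self.type1),
                          type2=tuple(u + c for u in self.type2))

    # difference accessors, in the anchoring-free sense
    @property
    def benefit2(self) -> float:
        return self.type2[0] - self.type2[2]

    @property
    def harm2(self) -> float:
        return self.type2[3] - self.type2[1]

    @property
    def benefit1(self) -> float:
        return self.type1[0] - self.type1[2]

    @property
    def harm1(self) -> float:
        return self.type1[3] - self.type1[1]


@dataclass(frozen=True)
class Scenario:
    """A complete decision problem: treatment, test, cognitive weight and
    (optionally) the patient's probability of disease."""

    treatment: TreatmentProfile
    test: TestProfile
    weight: CognitiveWeight
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p is not None:
            _check_prob("disease probability p", self.p)


@dataclass(frozen=True)
class ThresholdSet:
    """All thresholds of a scenario, clamped to [0, 1].

    ``pt_*`` are the two-strategy (treat vs. no-treat, no test available)
    thresholds; ``ptt_*`` / ``prx_*`` the testing and treatment thresholds
    of the three-strategy problem.  ``raw_*`` are the pre-clamp values,
    which may leave [0, 1] and carry the sign information used by the
    regime classification.  ``pt_rg`` is ``None`` when type-1 regrets were
    not elicited.
    """

    pt_eut: float
    pt_rg: Optional[float]
    pt_dpm: float
    ptt_eut: float
    prx_eut: float
    ptt_dpm: float
    prx_dpm: float
    raw_pt_dpm: float
    raw_ptt_dpm: float
    raw_prx_dpm: float
    include_test_harm: bool = False

    def to_dict(self) -> dict:
        """Lossless dict form (full float precision), for JSON round-trips."""
        return {
            "pt_eut": self.pt_eut,
            "pt_rg": self.pt_rg,
            "pt_dpm": self.pt_dpm,
            "ptt_eut": self.ptt_eut,
            "prx_eut": self.prx_eut,
            "ptt_dpm": self.ptt_dpm,
            "prx_dpm": self.prx_dpm,
            "raw_pt_dpm": self.raw_pt_dpm,
            "raw_ptt_dpm": self.raw_ptt_dpm,
            "raw_prx_dpm": self.raw_prx_dpm,
            "include_test_harm": self.include_test_harm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(**d)


def utilities_from_profiles(t: TreatmentProfile) -> UtilitySet:
    """Anchored utility set of a treatment profile (see
    :meth:`UtilitySet.from_treatment`)."""
    return UtilitySet.from_treatment(t)


def validate_scenario(s: Scenario, *, for_test_thresholds: bool = False,
                      for_sign_rules: bool = False,
                      require_type1: bool = False) -> Scenario:
    """Re-assert every invariant of a scenario and return it unchanged.

    Constructors already validate their own fields; this adds the
    contextual cross-object checks:

    * ``specificity < 1`` when the testing-threshold closed form will be
      evaluated (it divides by ``1 - specificity``), and ``gamma``
      bounded away from 1 (the closed forms divide by ``1 - gamma``);
    * the test objectively less harmful than the treatment
      (``test.harm < treatment.harm``) when the threshold ordering rules
      are asserted — the premise under which they are stated.

    Raises
    ------
    DomainError
        naming the violated constraint.
    """
    if for_sign_rules and s.test.harm >= s.treatment.harm:
        raise DomainError(
            "threshold ordering rules assume the test is less harmful than "
            f"the treatment: got test.harm={s.test.harm!r} >= "
            f"treatment.harm={s.treatment.harm!r}")
    if for_test_thresholds:
        if s.test.specificity >= 1.0:
            raise DomainError(
                "testing threshold is undefined at specificity = 100% "
                "(the closed form divides by 1 - Sp)")
        if s.weight.is_type1_only:
            raise DomainError(
                "closed-form thresholds are invalid at gamma = 1; use the "
                "pure type-1 decision rule instead")
    if require_type1:
        s.treatment.require_type1()
    return s
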