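"""Bundled case-study presets, threshold sweeps and a scenario sampler.

The presets encode the published prostate-cancer decision problem: a
patient with elevated PSA and abnormal digital rectal examination, the
choice being observation, transrectal-ultrasound-guided biopsy (the
diagnostic test) or immediate radical prostatectomy (the treatment).
Evidence-based inputs: absolute survival benefit of prostatectomy 2.5%
to 10%, harm 0.4% (mortality) or 37% (erectile dysfunction, the harm
that dominates for patients with long life expectancy), biopsy mortality
0.09%, biopsy sensitivity 86% and specificity 94%.  Type-1 regrets are
deliberately left unelicited — they belong to the individual decision
maker.

Sweeps trace the thresholds as the intuited benefit/harm ratio of
treatment varies for several levels of intuited test harm, the structure
of the published threshold-curve figures.  Because the closed forms need
the *absolute* regret of commission, not just the ratio, the sweep
requires an explicit anchor for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CognitiveWeight,
    DomainError,
    Scenario,
    TestProfile,
    TreatmentProfile,
)
from . import thresholds as th
from .decision_tree import _type1_only_action

__all__ = [
    "prostate_presets",
    "SweepSpec",
    "SWEEP_COLUMNS",
    "sweep_thresholds",
    "sample_scenarios",
]

_BIOPSY = dict(sensitivity=0.86, specificity=0.94, harm=0.0009)


def prostate_presets() -> Dict[str, Scenario]:
    """The bundled prostate-cancer scenarios.

    * ``mortality`` — survival benefit 10%, treatment harm = operative
      mortality 0.4%;
    * ``mortality-min-benefit`` — same, with the low end of the benefit
      range (2.5%);
    * ``erectile-dysfunction`` — benefit 10%, harm = erectile
      dysfunction 37%.

    All share the biopsy test profile (S=86%, Sp=94%, objective harm
    0.09%) and carry gamma = 0 and unelicited type-1 regrets; use
    :meth:`TreatmentProfile.with_regrets` and a nonzero weight to obtain
    the dual-process thresholds.
    """
    def make(benefit: float, harm: float) -> Scenario:
        return Scenario(
            treatment=TreatmentProfile(benefit=benefit, harm=harm),
            test=TestProfile(**_BIOPSY),
            weight=CognitiveWeight(gamma=0.0),
        )

    return {
        "mortality": make(0.10, 0.004),
        "mortality-min-benefit": make(0.025, 0.004),
        "erectile-dysfunction": make(0.10, 0.37),
    }


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a threshold sweep.

    ``ratios`` are intuited benefit/harm ratios (regret of omission over
    regret of commission); ``regret_commission`` anchors the absolute
    regret scale, so each grid point uses
    ``regret_omission = ratio * regret_commission``.  ``test_regrets``
    lists type-1 test harms.  ``gamma = None`` derives the weight at each
    grid point from the distance between the analytic and regret
    thresholds (the model's own elicitation rule); a float fixes it.
    """

    base: Scenario
    ratios: Sequence[float]
    regret_commission: float
    test_regrets: Sequence[float] = (0.0,)
    gamma: Optional[float] = None
    include_test_harm: bool = False

    def __post_init__(self) -> None:
        if not self.ratios or not self.test_regrets:
            raise DomainError("sweep grids must be non-empty")
        if any(r < 0 for r in self.ratios):
            raise DomainError("benefit/harm ratios must be >= 0")
        if self.regret_commission <= 0:
            raise DomainError(
                f"regret_commission anchor must be > 0, "
                f"got {self.regret_commission!r}")
        if self.gamma is not None and not (0.0 <= self.gamma <= 1.0):
            raise DomainError(f"gamma must lie in [0, 1], got {self.gamma!r}")


#: Fixed column order of sweep tables (also the CSV header order).
SWEEP_COLUMNS = [
    "ratio", "test_regret", "gamma", "type1_only",
    "pt_eut", "pt_rg", "pt_dpm",
    "ptt_eut", "prx_eut", "ptt_dpm", "prx_dpm",
    "testing_regime", "treatment_regime", "inverted_window", "action",
]


def _sweep_row(spec: SweepSpec, ratio: float, test_regret: float) -> dict:
    """One grid point; a pure function of (base, ratio, test_regret, rule)."""
    base = spec.base
    treatment = base.treatment.with_regrets(
        omission=ratio * spec.regret_commission,
        commission=spec.regret_commission)
    pt_eut = th.eut_threshold(treatment.benefit, treatment.harm)
    pt_rg = th.regret_threshold(*treatment.require_type1())
    if spec.gamma is None:
        weight = th.derive_gamma(pt_eut, pt_rg)
    else:
        weight = CognitiveWeight(gamma=spec.gamma)
    test = TestProfile(sensitivity=base.test.sensitivity,
                       specificity=base.test.specificity,
                       harm=base.test.harm, regret=test_regret)
    scenario = Scenario(treatment=treatment, test=test, weight=weight)
    row = {"ratio": ratio, "test_regret": test_regret,
           "gamma": weight.gamma, "pt_eut": pt_eut, "pt_rg": pt_rg}
    if weight.is_type1_only:
        # closed forms invalid: flag the row and report the pure type-1
        # action instead of thresholds
        action = _type1_only_action(scenario)
        row.update(type1_only=True, pt_dpm=np.nan,
                   ptt_eut=np.nan, prx_eut=np.nan,
                   ptt_dpm=np.nan, prx_dpm=np.nan,
                   testing_regime="", treatment_regime="",
                   inverted_window=False, action=action.choice.value)
        return row
    ts = th.threshold_set(scenario, include_test_harm=spec.include_test_harm)
    regime = th.classify_regime(scenario,
                                include_test_harm=spec.include_test_harm)
    row.update(type1_only=False, pt_dpm=ts.pt_dpm,
               ptt_eut=ts.ptt_eut, prx_eut=ts.prx_eut,
               ptt_dpm=ts.ptt_dpm, prx_dpm=ts.prx_dpm,
               testing_regime=regime.testing,
               treatment_regime=regime.treatment,
               inverted_window=regime.inverted_window, action="")
    return row


def sweep_thresholds(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the thresholds over the (ratio, test-regret) grid.

    One row per grid point, columns in :data:`SWEEP_COLUMNS`.  The EUT
    columns are constant across ratios (intuition does not enter them);
    rows where the derived gamma reaches 1 are flagged ``type1_only``
    and carry the pure type-1 action in place of thresholds.
    """
    rows = [_sweep_row(spec, r, hit)
            for hit in spec.test_regrets for r in spec.ratios]
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def sample_scenarios(n: int, seed: int) -> List[Scenario]:
    """Draw ``n`` reproducible random valid scenarios for property tests.

    Sampling ranges: benefits, harms and regrets uniform on (0.01, 1];
    sensitivity and specificity uniform on (0.5, 0.999); gamma uniform on
    [0, 0.95] (bounded away from the type-1-only singularity); objective
    test harm uniform on (0, 0.5 * Sp * harm) so the test is always
    objectively less harmful than the treatment; type-1 test regret
    uniform on [0, 0.3]; disease probability uniform on [0, 1].  The
    ranges straddle both sign-rule regimes and both window orderings.
    """
    if n <= 0:
        raise DomainError(f"n must be positive, got {n!r}")
    rng = np.random.default_rng(seed)
    out: List[Scenario] = []
    for _ in range(n):
        benefit = rng.uniform(0.01, 1.0)
        harm = rng.uniform(0.01, 1.0)
        b1 = rng.uniform(0.01, 1.0)
        h1 = rng.uniform(0.01, 1.0)
        s = rng.uniform(0.5, 0.999)
        sp = rng.uniform(0.5, 0.999)
        test_harm = rng.uniform(0.0, 0.5 * sp * harm)
        test_regret = rng.uniform(0.0, 0.3)
        gamma = rng.uniform(0.0, 0.95)
        p = rng.uniform(0.0, 1.0)
        out.append(Scenario(
            treatment=TreatmentProfile(benefit=benefit, harm=harm,
                                       regret_omission=b1,
                                       regret_commission=h1),
            test=TestProfile(sensitivity=s, specificity=sp,
                             harm=test_harm, regret=test_regret),
            weight=CognitiveWeight(gamma=gamma),
            p=p,
        ))
    return out
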