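"""Configuration loading for scenarios and sweeps.

Config files are YAML (JSON, being a YAML subset, also parses).  All
probabilities, utilities and regrets may be written either as fractions
(``0.004``) or as percent strings (``"0.4%"``); percent values are
normalized to fractions on load and the normalized values are echoed to
the log.  Unknown keys are rejected rather than ignored.

Schema::

    treatment:
      benefit: 10%            # required  (B)
      harm: 0.4%              # required  (H)
      regret_omission: 0.3    # optional  (B_I), with regret_commission
      regret_commission: 0.6  # optional  (H_I)
    test:
      sensitivity: 86%        # required  (S)
      specificity: 94%        # required  (Sp)
      harm: 0.09%             # optional  (H_T),  default 0
      regret: 0.1             # optional  (H_IT), default 0
    gamma: 0.2                # optional, default 0
    p: 10%                    # optional
    include_test_harm: false  # optional
    sweep:                    # optional
      ratios: [0.5, 1, 2]
      regret_commission: 0.5
      test_regrets: [0, 0.1]
      gamma: null             # null -> derived per grid point
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .core import (
    CognitiveWeight,
    DomainError,
    Scenario,
    TestProfile,
    TreatmentProfile,
)
from .scenarios import SweepSpec

__all__ = ["RunConfig", "load_config", "parse_quantity"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """A validated run: the scenario plus evaluation options."""

    scenario: Scenario
    include_test_harm: bool = False
    sweep: Optional[SweepSpec] = None


def parse_quantity(value: Union[int, float, str], name: str) -> float:
    """Normalize a number or percent string to a fraction.

    ``"0.4%"`` -> 0.004; plain numbers pass through unchanged.
    """
    if isinstance(value, bool) or not isinstance(value, (int, float, str)):
        raise DomainError(f"{name}: expected a number or percent string, "
                          f"got {value!r}")
    if isinstance(value, str):
        text = value.strip()
        if not text.endswith("%"):
            raise DomainError(
                f"{name}: string values must be percentages like '0.4%', "
                f"got {value!r}")
        try:
            return float(text[:-1]) / 100.0
        except ValueError:
            raise DomainError(f"{name}: cannot parse percentage {value!r}")
    return float(value)


def _take(mapping: dict, context: str, required: dict, optional: dict) -> dict:
    """Pull and normalize fields, rejecting unknown keys.

    ``required`` / ``optional`` map config key -> conventional symbol
    used in error messages; optional fields default to None.
    """
    if not isinstance(mapping, dict):
        raise DomainError(f"{context}: expected a mapping, got {mapping!r}")
    unknown = set(mapping) - set(required) - set(optional)
    if unknown:
        raise DomainError(
            f"{context}: unknown key(s) {sorted(unknown)}")
    out = {}
    for key, symbol in required.items():
        if key not in mapping:
            raise DomainError(
                f"{context}: missing required field '{key}' ({symbol})")
        out[key] = parse_quantity(mapping[key], f"{context}.{key}")
    for key in optional:
        out[key] = (parse_quantity(mapping[key], f"{context}.{key}")
                    if key in mapping and mapping[key] is not None else None)
    return out


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Raises
    ------
    DomainError
        naming the offending field and constraint; YAML syntax errors
        propagate with line context from the parser.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DomainError(f"{path}: config root must be a mapping")

    top_keys = {"treatment", "test", "gamma", "p", "include_test_harm",
                "sweep"}
    unknown = set(raw) - top_keys
    if unknown:
        raise DomainError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    if "treatment" not in raw:
        raise DomainError(f"{path}: missing required section 'treatment'")
    if "test" not in raw:
        raise DomainError(f"{path}: missing required section 'test'")

    t = _take(raw["treatment"], "treatment",
              required={"benefit": "B", "harm": "H"},
              optional={"regret_omission": "B_I", "regret_commission": "H_I"})
    treatment = TreatmentProfile(**t)

    te = _take(raw["test"], "test",
               required={"sensitivity": "S", "specificity": "Sp"},
               optional={"harm": "H_T", "regret": "H_IT"})
    test = TestProfile(sensitivity=te["sensitivity"],
                       specificity=te["specificity"],
                       harm=te["harm"] or 0.0,
                       regret=te["regret"] or 0.0)

    gamma = parse_quantity(raw.get("gamma", 0.0), "gamma")
    p = (parse_quantity(raw["p"], "p")
         if raw.get("p") is not None else None)
    include_test_harm = bool(raw.get("include_test_harm", False))

    scenario = Scenario(treatment=treatment, test=test,
                        weight=CognitiveWeight(gamma=gamma), p=p)

    sweep = None
    if raw.get("sweep") is not None:
        sw = raw["sweep"]
        if not isinstance(sw, dict):
            raise DomainError("sweep: expected a mapping")
        sw_keys = {"ratios", "regret_commission", "test_regrets", "gamma"}
        unknown = set(sw) - sw_keys
        if unknown:
            raise DomainError(f"sweep: unknown key(s) {sorted(unknown)}")
        if "ratios" not in sw:
            raise DomainError("sweep: missing required field 'ratios' "
                              "(B_I/H_I grid)")
        if "regret_commission" not in sw:
            raise DomainError("sweep: missing required field "
                              "'regret_commission' (H_I anchor)")
        ratios = [parse_quantity(r, "sweep.ratios") for r in sw["ratios"]]
        test_regrets = [parse_quantity(v, "sweep.test_regrets")
                        for v in sw.get("test_regrets", [0.0])]
        sweep_gamma = (parse_quantity(sw["gamma"], "sweep.gamma")
                       if sw.get("gamma") is not None else None)
        sweep = SweepSpec(
            base=scenario, ratios=ratios,
            regret_commission=parse_quantity(
                sw["regret_commission"], "sweep.regret_commission"),
            test_regrets=test_regrets, gamma=sweep_gamma,
            include_test_harm=include_test_harm)

    logger.info("loaded config %s: B=%g H=%g S=%g Sp=%g gamma=%g",
                path, treatment.benefit, treatment.harm, test.sensitivity,
                test.specificity, gamma)
    return RunConfig(scenario=scenario, include_test_harm=include_test_harm,
                     sweep=sweep)
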