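"""Recommended actions across the probability range.

Compares the threshold-window rule with direct valuation argmax on the
mortality-focused prostate scenario, then shows the pure-intuition
special case: at gamma = 1 the test drops out entirely and the choice
reduces to comparing the two regrets.
"""

import dataclasses

from dpmdx import (
    CognitiveWeight,
    prostate_presets,
    recommend_by_threshold,
    recommend_by_valuation,
)

base = prostate_presets()["mortality"]
grid = [0.001, 0.01, 0.05, 0.10, 0.20, 0.25, 0.50, 0.90]

print("gamma = 0 (pure analysis), test harm excluded from the EUT limits:")
for p in grid:
    a = recommend_by_threshold(base, p)
    print(f"  p = {p:5.3f}  ->  {a.choice.value:<5} ({a.provenance})")

print()
print("same scenario, valuation argmax (carries the 0.09% biopsy harm):")
for p in grid:
    a = recommend_by_valuation(base, p)
    print(f"  p = {p:5.3f}  ->  {a.choice.value:<5} ({a.provenance})")

print()
intuitive = dataclasses.replace(
    base,
    treatment=base.treatment.with_regrets(omission=0.8, commission=0.3),
    weight=CognitiveWeight(1.0))
a = recommend_by_threshold(intuitive, 0.05)
print(f"gamma = 1, omission regret 0.8 > commission regret 0.3, p = 0.05:"
      f"  {a.choice.value} ({a.provenance})")
print("Pure intuition ignores the probability and the test: it treats")
print("whenever the regret of not treating outweighs the regret of")
print("treating needlessly.")
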