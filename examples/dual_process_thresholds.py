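"""Blending intuition into the thresholds.

Starting from the erectile-dysfunction scenario, we elicit the decision
maker's regrets — regret of omission 0.2 (missing a cancer), regret of
commission 0.4 (operating needlessly) and a felt biopsy harm of 0.1 —
derive the cognitive weight gamma from the distance between the analytic
and regret thresholds, and compare the dual-process thresholds with the
expected-utility ones.
"""

import dataclasses

from dpmdx import (
    Scenario,
    classify_regime,
    derive_gamma,
    eut_threshold,
    percent,
    prostate_presets,
    regret_threshold,
    threshold_set,
)

base = prostate_presets()["erectile-dysfunction"]
treatment = base.treatment.with_regrets(omission=0.2, commission=0.4)
test = dataclasses.replace(base.test, regret=0.1)

pt_eut = eut_threshold(treatment.benefit, treatment.harm)
pt_rg = regret_threshold(treatment.regret_omission,
                         treatment.regret_commission)
weight = derive_gamma(pt_eut, pt_rg)
print(f"analytic treatment threshold  {pt_eut:.4f}")
print(f"regret treatment threshold    {pt_rg:.4f}")
print(f"derived cognitive weight      gamma = {weight.gamma:.4f}")

scenario = Scenario(treatment=treatment, test=test, weight=weight)
ts = threshold_set(scenario)
regime = classify_regime(scenario)

print()
print(f"{'':<22}{'EUT':>10}{'DPM':>10}")
print(f"{'testing threshold':<22}{ts.ptt_eut:>10.4f}{ts.ptt_dpm:>10.4f}"
      f"   ({percent(ts.ptt_eut)}% -> {percent(ts.ptt_dpm)}%, "
      f"{regime.testing})")
print(f"{'treatment threshold':<22}{ts.prx_eut:>10.4f}{ts.prx_dpm:>10.4f}"
      f"   ({percent(ts.prx_eut)}% -> {percent(ts.prx_dpm)}%, "
      f"{regime.treatment})")

print()
print("The felt harms of treatment and biopsy outweigh the felt benefit")
print("(H_I + 4*H_IT > B_I), so intuition demands more certainty before")
print("testing; but H_I < B_I + 4*H_IT, so it settles for treatment at a")
print("slightly lower probability than pure analysis would.")
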