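"""Prostate-cancer case study: expected-utility thresholds.

A 66-year-old patient has an elevated PSA and an abnormal digital rectal
exam.  The options are observation, a prostate biopsy (sensitivity 86%,
specificity 94%, mortality 0.09%), or immediate radical prostatectomy
(survival benefit up to 10%).  Under pure analytic weighting (gamma = 0)
the thresholds depend on which treatment harm dominates the decision.
"""

from dpmdx import eut_test_thresholds, percent, prostate_presets

presets = prostate_presets()

for name in ("mortality", "mortality-min-benefit", "erectile-dysfunction"):
    s = presets[name]
    ptt, prx = eut_test_thresholds(s.treatment, s.test)
    print(f"{name:<24} testing threshold {ptt:.4f} ({percent(ptt)}%)   "
          f"treatment threshold {prx:.4f} ({percent(prx)}%)")

print()
print("Reading: below the testing threshold, observe; between the two,")
print("biopsy; above the treatment threshold, operate without a biopsy.")
print("With only operative mortality (0.4%) as the harm, expected utility")
print("recommends biopsy at the slightest suspicion (0%) and surgery")
print("above 21% — thresholds few clinicians would accept.  Counting")
print("erectile dysfunction (37%) as the harm raises the biopsy bar to 21%.")
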