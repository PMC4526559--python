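# dpmdx — dual-process testing and treatment thresholds

`dpmdx` computes clinical decision thresholds for the three-way choice a
clinician faces when a diagnostic test is available: **observe** the
patient, **order the test** and act on its result, or **treat**
immediately. It implements the dual-processing extension of the classic
threshold model, in which the thresholds blend analytic, expected-utility
reasoning with intuitive, regret-based reasoning. It is aimed at medical
decision scientists, health-economics modellers and educators who want
reproducible threshold calculations rather than ad-hoc spreadsheet
algebra.

## The model

Under expected utility theory (EUT) the treatment threshold — the disease
probability *p* at which treating and not treating are equally good — is

```
p_t,EUT = 1 / (1 + B/H)
```

with *B* the net benefit of treating the diseased and *H* > 0 the net
harm of treating the healthy. With a test of sensitivity *S* and
specificity *Sp* the single threshold splits into a *testing threshold*
`p_tt` (below it, do nothing) and a *treatment threshold* `p_rx` (above
it, treat without testing); testing is worthwhile in between.

Dual-process theory adds a second, intuitive valuation in which **regret
of omission** `B_I` (failing to treat disease) plays the role of benefit
and **regret of commission** `H_I` (treating the healthy) the role of
harm, with `H_IT` the felt harm of the test itself. A cognitive weight
γ ∈ [0, 1] sets how much intuition contributes (γ = 0 pure analysis,
γ = 1 pure intuition). The dual-process thresholds multiply each EUT
threshold by a bracket carrying the intuitive tilt, e.g. for the
two-strategy problem

```
p_t = p_t,EUT · [1 + γ/(2(1−γ)) · (H_I/H)(1 − B_I/H_I)]
```

and analogously (with γ/(4(1−γ)) and test-harm terms) for `p_tt` and
`p_rx`. Consequences the package computes and tests:

- γ = 0 recovers the EUT thresholds exactly; balanced regrets
  (`B_I = H_I`) with a harmless test are neutral at every γ;
- intuition **raises** the testing threshold iff `H_I + 4·H_IT > B_I`
  and the treatment threshold iff `H_I > B_I + 4·H_IT` — test accuracy
  never changes the direction;
- the treatment threshold can drop **below** the testing threshold
  (an inverted window, irrational under EUT but observed in practice);
- at γ = 1 the closed forms are invalid, testing never wins, and the
  choice reduces to `B_I > H_I`.

Every closed form is cross-checked against an independent decision-tree
valuation engine: the three strategy valuations are affine in *p*, so
each indifference probability is the root of a linear equation that the
`decision_tree` module solves numerically.

## Worked example

The bundled prostate-cancer presets describe a patient with elevated PSA
and abnormal rectal exam: biopsy (S = 86%, Sp = 94%, mortality 0.09%)
versus radical prostatectomy (survival benefit up to 10%; harm either
operative mortality 0.4% or erectile dysfunction 37%).

```sh
$ python examples/case_study.py
mortality                testing threshold 0.0028 (0%)   treatment threshold 0.2117 (21%)
mortality-min-benefit    testing threshold 0.0110 (1%)   treatment threshold 0.5179 (52%)
erectile-dysfunction     testing threshold 0.2052 (21%)   treatment threshold 0.9613 (96%)
```

Focusing only on mortality, expected utility says to biopsy at the
slightest suspicion of cancer (testing threshold 0%) and to operate above
21% — recommendations few clinicians or patients would accept. Counting
erectile dysfunction as the harm raises the biopsy bar to 21%. Adding
intuition shifts the thresholds per decision maker:

```sh
$ python examples/dual_process_thresholds.py
analytic treatment threshold  0.7872
regret treatment threshold    0.6667
derived cognitive weight      gamma = 0.1532

                             EUT       DPM
testing threshold         0.2052    0.2061   (21% -> 21%, raised)
treatment threshold       0.9613    0.9393   (96% -> 94%, lowered)
```

Here the felt harms of surgery and biopsy outweigh the felt benefit
(`H_I + 4·H_IT > B_I`), so this decision maker wants slightly more
certainty before a biopsy, yet accepts surgery a little earlier than
pure analysis would. The same computations are available from the shell:

```sh
dpmdx thresholds --preset mortality --gamma 0
dpmdx recommend --preset mortality --gamma 0 --p 0.10     # -> Test
dpmdx sweep --preset erectile-dysfunction --ratios 0.125:8:25 \
      --test-regrets 0,0.1,0.2 --out curves.csv
```

See `examples/` for threshold sweeps over the regret ratio and the
recommendation rules including the pure-intuition special case.

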