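# Methods

## Model

The package implements the threshold framework for the three-strategy
clinical problem — observe (`NoRx`), test (`Test`), treat (`Rx`) — under
a dual-process valuation. A strategy's value is a convex blend of a
type-2 (analytic, expected-utility) component and a type-1 (intuitive,
regret-based) component, weighted by the cognitive weight γ:

```
V(Rx)   = γ/2 (U1_2 − U1_4) + (1−γ)[p·U2_1 + (1−p)·U2_2]
V(NoRx) = γ/2 (U1_3 − U1_1) + (1−γ)[p·U2_3 + (1−p)·U2_4]
V(T)    = γ/4 (U1_2 − U1_4 + U1_3 − U1_1)
          + (1−γ)[p·S·U2_1 + (1−p)(1−Sp)·U2_2 + p(1−S)·U2_3 + (1−p)·Sp·U2_4]
          − (γ·H_IT + (1−γ)·H_T)
```

Outcome indices: 1 treated/diseased, 2 treated/healthy, 3
untreated/diseased, 4 untreated/healthy. The type-1 utilities are regret
valuations; their differences define the regret of omission
`B_I = U1_1 − U1_3` and of commission `H_I = U1_4 − U1_2`, the type-1
analogues of the evidence-based benefit `B = U2_1 − U2_3` and harm
`H = U2_4 − U2_2`.

Setting `V(Rx) = V(NoRx)`, `V(NoRx) = V(T)` and `V(Rx) = V(T)` and
solving for *p* yields, respectively, the two-strategy treatment
threshold, the testing threshold `p_tt` and the treatment threshold
`p_rx`, each expressed as the γ = 0 (EUT) threshold times a bracket
carrying the intuitive tilt `(H_I/H)(1 − B_I/H_I) = (H_I − B_I)/H` and,
for the test thresholds, the test-harm terms.

### Assumptions

- Benefits, harms and regrets are dimensionless utilities on a common
  [0, 1]-anchored scale; only differences enter any result, so the
  anchor is a free convention. The package anchors the two "correct
  inaction" outcomes at 0; an affine-invariance test verifies that
  shifting all eight utilities changes no valuation difference and no
  indifference probability.
- One scalar benefit and one scalar harm per cognitive mode. Published
  evidence tables list several component harms (mortality, erectile
  dysfunction, incontinence, …); how to aggregate them into one scalar
  is not part of the model, so each preset carries a single dominant
  harm and aggregation is left to the user.
- `H > 0` and `H_I > 0` strictly (every real treatment harms someone;
  the closed forms divide by them). The test is assumed objectively
  less harmful than the treatment (`H_T < H`) where the
  threshold-ordering rules are asserted.

## Parameters

| symbol | meaning | units | default |
|---|---|---|---|
| `B`, `H` | type-2 treatment benefit / harm | utility (fraction) | required |
| `B_I`, `H_I` | regret of omission / commission | utility | unelicited |
| `S`, `Sp` | test sensitivity / specificity | probability | required |
| `H_T`, `H_IT` | type-2 / type-1 test harm | utility | 0 |
| `γ` | weight of type-1 processes | — | 0 |
| `p` | probability of disease | probability | optional |

γ may be supplied directly or derived as
`min(|p_t,EUT − p_t,RG| / p_t,EUT, 1)` — the relative distance between
the analytic and regret thresholds, the model's own elicitation rule and
the default in sweeps.

### Prostate presets

`mortality` (B = 0.10, H = 0.004), `mortality-min-benefit` (B = 0.025)
and `erectile-dysfunction` (H = 0.37) share the biopsy profile
S = 0.86, Sp = 0.94, H_T = 0.0009. Type-1 regrets are deliberately
unelicited: they belong to the individual decision maker.

## Numerical and design choices

- **Test-harm convention (κ).** The γ = 0 limits are
  `p_tt,EUT = ((1−Sp)H + κ·H_T)/(S·B + (1−Sp)H)` and
  `p_rx,EUT = (Sp·H − κ·H_T)/((1−S)B + Sp·H)`. The default κ = 0
  (test harm excluded) reproduces the case study's printed values
  (0%, 21%, 21%); κ = 1 gives the exact γ = 0 indifference points of
  the tree valuations and is used by the recommender-consistency test.
  Note the closed-form brackets of `p_tt`/`p_rx` carry `H_T`
  multiplicatively while the tree solution carries it additively; the
  two routes are therefore compared only where they agree exactly (the
  two-strategy threshold, below).
- **Clamping.** Public thresholds are clamped to [0, 1]; the brackets
  can go negative when one regret dominates strongly, and a negative
  threshold means "act at any probability". Pre-clamp values are kept
  on the `ThresholdSet` — sign and monotonicity properties (including
  window inversion) are stated on them.
- **γ guard.** The brackets divide by 1 − γ; weights within 1e−9 of 1
  are treated as the pure type-1 case. Thresholds then raise a domain
  error, while the recommender logs a warning and applies the type-1
  rule: treat iff `B_I > H_I`, never test.
- **Ordering rules.** Raised-vs-lowered labels follow the bracket
  signs: testing raised iff `H_I + 4·H_IT > B_I`; treatment raised iff
  `H_I > B_I + 4·H_IT` (requiring `H_T < Sp·H`). Exact equality is
  labelled "unchanged". (The published prose prints the same inequality
  for both directions of the testing rule — a typo; the bracket sign is
  unambiguous.)
- **Indifference oracle.** Each valuation is affine in *p*, so the
  solver computes the root of the pairwise difference from its values
  at p = 0 and p = 1, with a Brent bracketing fall-back kept for
  robustness if the valuation forms are ever extended. The pre-clamp
  two-strategy threshold equals this root identically under the
  anchoring convention; the test suite asserts agreement to 1e−9 on
  1,000 random scenarios.
- **Inverted window.** When `p_rx ≤ p_tt` no probability range favours
  testing. The published model notes the phenomenon but gives no
  decision rule; the threshold recommender then drops `Test` and
  decides treat-vs-observe by the two-strategy threshold, while the
  valuation-argmax recommender remains available as the model-faithful
  alternative. Both record their provenance on the returned `Action`.
- **Ties.** Exact valuation ties go to the least interventional
  strategy (observe over test over treat) — primum non nocere, and ties
  are measure-zero.
- **Reporting.** Tables round to whole percents, half away from zero
  (20.518% → 21%), matching the case study's reporting style; CSV/JSON
  output keeps 6 significant digits and the JSON round-trip is lossless.
- **Sweeps.** The threshold-curve figures plot against the ratio
  `B_I/H_I`, but the brackets need the absolute `H_I`; the absolute
  regret scale behind the published curves is unstated, so `SweepSpec`
  requires an explicit `regret_commission` anchor and no published curve
  is treated as ground truth. CLI ratio grids are geometrically spaced
  (the published panels span a log-symmetric 1/8×–8× range).

## Known discrepancies of the published example

- The fourth printed case-study value (treatment threshold "49%" for
  the erectile-dysfunction scenario) is not reproducible from any
  formula consistent with the other three printed values; the closed
  form gives 96.1%. It is excluded from testing and recorded here.
- The remark that `p_tt,EUT → 1` as `Sp → 100%` holds for the κ = 1
  (harm-inclusive) form but not for the κ = 0 form that reproduces the
  printed values (which → 0). The limit is recorded, not asserted; both
  forms raise a domain error exactly at Sp = 100%.

## Synthetic scenarios

`sample_scenarios(n, seed)` draws property-test scenarios: benefits,
harms and regrets uniform on (0.01, 1]; S, Sp uniform on (0.5, 0.999);
γ uniform on [0, 0.95]; `H_T` uniform on (0, 0.5·Sp·H) so the ordering
rules' premise holds for every draw; `H_IT` uniform on [0, 0.3];
p uniform on [0, 1]. These ranges cover both ordering regimes and both
window orderings. The generator emulates the *parameter space* of the
model, not empirical practice: real elicited regrets are bounded by
instrument granularity, correlate with the evidence-based harms, and
cluster by clinician — none of which is modelled. Passing property
suites therefore establishes the algebraic guarantees of the
implementation, not the behavioural accuracy of the model on real
decision makers.

The randomized suites use 1,000 scenarios (200 for the γ-grid
neutrality sweep and the affine-grid checks), sizes at which every suite
completes in well under ten seconds while exercising both branches of
each sign rule hundreds of times.

## Limitations

- Single test, single administration: no test sequences, retesting or
  imperfect gold standards.
- No uncertainty propagation: thresholds are point values, without
  confidence intervals on the input benefits/harms.
- Multi-outcome aggregation into the scalar harms is out of scope.
- The regret-elicitation instrument (dual visual analogue scales) is
  outside the package; its outputs are the model's inputs.
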