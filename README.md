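# voiredist

Analysis pipeline for a **veil-of-ignorance (VoI) redistribution game**:
a behavioural-neuroscience paradigm in which participants in a hypothetical
three-class society (high / middle / low income) repeatedly choose one of
three redistribution rules — *inequality* (status quo), *intermediate*
(partial transfer), or *equality* (full equalisation) — while 25 % of every
transferred amount is lost as a deadweight cost. Decisions are made either
behind the VoI (the decider's own class is hidden) or informed of the
assigned class; society outcomes are fixed by majority vote or by a
dictator, and lottery rounds with the same screen format serve as a
self-risk control.

The package is aimed at researchers who want to re-run, stress-test, or
extend every analysis stage of such an experiment without access to the
original participant data: all inputs can be simulated with the statistical
structure the analyses assume, and real data can be ingested from
documented long-format CSVs.

## What it computes

* **Game engine** — payoff schemes with a cost-bearing transfer schedule
  (the equality rule is exactly feasible only when
  `m − l = (1 − cost_rate)(h − m)`), society-level decisions (majority
  vote with random split-vote resolution, or dictatorship), and
  selfless/selfish decision groupings by class interest.
* **Synthetic cohort** — 33 agents × 4 sessions (VoI/Informed ×
  Voting/Dictatorship) drawn from a softmax-utility policy mixture
  (expected-value vs maximin risk attitudes, fairness weights, lapse
  rate), with guaranteed coverage of every (class, societal outcome)
  pair, accumulated incomes, feeling-thermometer ratings, and a
  trial-level ROI outcome with a configurable condition × decision
  interaction.
* **Affect metrics** — affective changes from thermometer ratings I/II/III
  (`Δplay = II − I`, `Δdisclosure = III − II`), relative income
  (participant total / partners' total), and the **accordance /
  non-accordance** classification of higher-income cases by the sign of
  the disclosure change, with full exclusion accounting (zero-change and
  contradictory-session filters).
* **Interaction decomposition** — the baseline-invariant estimators

  ```
  τ(c₁,r₁; c₀,r₀) = Ȳ(c₁,r₁) − Ȳ(c₀,r₀)
  ψ(c₁; c₀)       = Σ_r [Ȳ(c₁,r) − Ȳ(c₀,r)] · P(r)
  ψ(r₁; r₀)       = Σ_c [Ȳ(c,r₁) − Ȳ(c,r₀)] · P(c)   (c ∈ {high, low, VoI})
  π                = τ − ψ(condition) − ψ(rule)
  ```

  where Ȳ are cell means of the trial outcome and P observed choice /
  condition frequencies. π is invariant to the choice of baseline: it is
  identically zero for additive tables and unchanged by constant shifts.
* **Inference** — per-participant choice-proportion and ever-chose
  summaries, Welch/pooled t tests, 2×2 χ² (with or without Yates
  correction), Pearson correlations, and a **participant-level cluster
  bootstrap** (whole participants resampled with replacement) with
  percentile confidence intervals.

## Worked example

```python
import voiredist as v

cfg = v.read_config(None, seed=1)        # all defaults, seed overridden
result = v.run_pipeline(cfg)             # simulate + all analysis stages
print(v.format_report(result))
```

prints (abridged):

```
Attitude classification accounting
  all cases:                    264
  higher-income cases:          161
  excluded, zero change:        49
  excluded, contradictory:      8 (from 4 sessions)
  retained:                     104
    accordance:                 33
    non-accordance:             71

Behavioural summaries (mean +/- sem across participants):
    voi equality_selfless      trials  29.0% +/-  3.7%
    voi non_equality_selfish   trials  71.0% +/-  3.7%
   high non_equality_selfish   trials  92.4% +/-  1.0%
    low non_equality_selfish   trials  91.2% +/-  1.5%

Interaction decomposition pi(voi,equality; high,inequality):
  tau = 0.3727  psi_condition = -0.3494  psi_rule = 0.4997  pi = 0.2225

Relative income vs disclosure change: r = -0.236 (p = 0.016)

Cluster bootstraps (percentile CI):
  attitude_signal_gap: 0.5017 [0.2229, 0.7965] (excludes 0.0: True)
  income_affect_r: -0.2357 [-0.4534, -0.0105] (excludes 0.0: True)
```

Reading the output: behind the VoI the synthetic cohort chooses a
non-equality rule in 71 % of trials (equality is cheap in expectation but
most agents are mild payoff maximisers), while informed agents are
overwhelmingly selfish. Of the 161 cases where a participant out-earned a
partner, 104 survive the exclusion filters and split into accordance
(rating drops after income disclosure) and non-accordance cases. The
positive π says the ROI outcome is super-additively elevated when an
equality decision is made behind the VoI, beyond the marginal effects of
condition and rule — the generator's interaction coefficient recovered
from the data. The negative correlation (r = −0.24) reproduces the
structure in which disclosure-related affective change declines with
relative income, and both bootstrap CIs exclude zero under
participant-level resampling.

The same stages are exposed on the command line:

```bash
voiredist simulate --config examples/default_config.yaml --seed 1 --out runs/demo
voiredist analyze decompose --in runs/demo
voiredist analyze bootstrap --in runs/demo -B 1000
voiredist report --in runs/demo
```

## Documentation

`docs/methods.md` describes the generative model, all tunable parameters
with their defaults and rationale, numerical choices, and the limits of
what the synthetic cohort can and cannot show about real data.
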