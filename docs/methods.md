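# Methods

## The game and its payoff scheme

A society of three income classes (high, middle, low) chooses among three
redistribution rules. Transfers flow only from the high to the low class
and a fraction `cost_rate` (default 0.25) of any transferred amount is
destroyed. The *equality* rule takes `T = h − m` from the high class and
delivers `(1 − cost_rate)·T` to the low class; the *intermediate* rule
transfers `intermediate_fraction·T` (default one half); *inequality*
transfers nothing. Absolute equality is exactly attainable only when the
pre-tax incomes satisfy the feasibility constraint

    m − l = (1 − cost_rate) · (h − m),

which `build_payoff_scheme` enforces (relative tolerance 1e-9). No
concrete class incomes are canonical for this paradigm, so the default
scheme is (h, m, l) = (2100, 1300, 700) points — round numbers satisfying
the constraint at cost rate 0.25, giving payoffs (2100, 1300, 700) /
(1700, 1300, 1000) / (1300, 1300, 1300) and total payouts 4100 / 4000 /
3900. The middle class is payoff-invariant across rules by construction;
consequently middle-class decisions carry no class interest and are
grouped as *neutral*.

Society outcomes: strict majority wins a vote; a three-way split is
resolved uniformly at random **among the cast votes** (randomising over
the tied alternatives, not over all rules). In dictatorship sessions the
dictator's choice stands.

Class-interest groupings: for the informed high class the selfish rule is
inequality and the selfless rules are intermediate and equality; for the
informed low class the selfish rule is equality and the selfless rules
are inequality and intermediate (choices that sacrifice one's own payoff
for the societal total).

## Synthetic cohort

The generator emulates the full study design: `n_participants` (default
33) each play four sessions, VoI/Informed crossed with
Voting/Dictatorship. Each session holds `rounds_per_session`
redistribution rounds (default 18, i.e. two full coverage cycles; the
number of rounds per session is not canonical, and 18 keeps every
condition × chosen-rule cell reliably populated at realistic choice
rates) plus `n_lottery` (default 6) randomly inserted lottery rounds.

**Coverage.** Rounds follow a shuffled schedule tiling all 9 (class,
societal outcome) pairs. Partners are simulated confederates whose votes
(or dictator choices) enact the scheduled outcome — mirroring a deception
design in which the society-level result is experimentally controlled —
so every pair is experienced in every session. In dictatorship sessions
roughly one third of rounds are self-dictated (the participant's own
choice becomes the outcome); these rounds are drawn so that at most one
scheduled copy of any pair is consumed, preserving coverage among the
society-decided rounds whenever the schedule holds ≥ 2 copies per pair.

**Choice policies.** Each agent draws a policy from a mixture of softmax
utility types. Utility of a rule is `w_self·own + w_total·total −
w_fair·spread`, with `own` the decider's payoff — behind the VoI either
the class-average payoff (expected-value type) or the minimum class
payoff (maximin type). The temperature is in money units per logit; a
lapse rate (`tremble`) mixes in a uniform choice, keeping every cell of
the factorial design reachable. The default mixture — 85 % mildly noisy
payoff maximisers (temperature 100), 8 % fairness-weighted agents
(`w_fair` = 0.25), 7 % maximin agents (temperature 80), all with lapse
rate 0.10 — was calibrated once, by hand, so the aggregate VoI
non-equality share sits near the low-70 % level characteristic of this
paradigm while informed decisions are overwhelmingly selfish. The true
decision process is of course unknown; this family merely spans the two
motivators the paradigm contrasts (consideration of others vs prospective
self-calculation) and is not an inference about real participants.

**Incomes.** Every player's per-round payoff (including lottery draws)
accumulates into a session total; partner lottery choices are drawn
uniformly since they affect only the partner's own total. Relative income
is the participant's session total divided by the two partners' summed
totals (parity ≈ 0.5). The balanced coverage schedule makes class
assignments nearly equal across players, so relative income varies only
through lottery draws and self-dictated rounds (sd ≈ 0.02 under
defaults) — a deliberately narrow spread that the affect generator takes
into account (below).

**Thermometer ratings.** A latent attitude (accordance with probability
`p_accordance` = 0.38) is drawn per participant-session; each
participant-partner pair copies it with probability
`attitude_correlation` = 0.8, else redraws — so contradictory sessions
(both attitudes shown in one session) arise at a controllable rate.
Rating I is N(46, 12²) truncated to [0, 100]. Play shifts the rating by
+10.4 (accordance) or −13.3 (non-accordance) degrees; disclosure shifts
it by −15.6 / +19.6 degrees respectively, plus `income_slope · (relative
income − 0.5)`. With probability `p_zero_change` (= 24/78) the disclosure
leaves the rating exactly unchanged. Gaussian noise (sd 6) is added to
the play and disclosure steps. Two numerical guards: ratings are clipped
to [0, 100], and the deterministic part of the disclosure change is
clamped to keep the latent attitude's sign (floor magnitude 1 degree), so
the latent attitude is exactly recoverable when noise is switched off.
The slope default (−150 degrees per unit ratio) is sized to the narrow
relative-income spread: it moves the disclosure change by a few degrees
over the observed range, producing the weak negative income–affect
correlation the analysis stage is meant to detect.

**Neural outcomes.** One continuous value per non-lottery trial, standing
in for ROI percent signal change *after* the redistribution-minus-lottery
subtraction (raw BOLD is never modelled):

    y = μ + a·1[equality rule] + b·1[VoI] + c·1[VoI-equality or informed-selfless]
        + d·1[accordance session] + s·relative_income·1[VoI-equality]
        + u_participant + ε,

with `u ~ N(0, 0.3²)`, `ε ~ N(0, 1)`. `a` (0.3) is the equality-rule main
effect, `b` (−0.2) the VoI main effect, and `c` (0.5) the condition ×
decision interaction aligned with the equality/selfless-versus-selfish
contrast — the quantity the decomposition recovers. `d` (0.4) elevates
accordance sessions and `s` (−0.5) adds a weak negative income dependence
on VoI-equality trials. Because the `d` and `s` terms load asymmetrically
on the (VoI, equality) cell, the interaction-recovery experiments set
them to zero: they are confounds by construction, and the recovery
question is about `c` alone.

## Affect classification

A *case* is a participant–partner–session triple. Classification is
restricted to cases where the participant's total exceeded that
partner's total (ties are out of scope): disclosure decrease ⇒
accordance, increase ⇒ non-accordance, exactly zero ⇒ excluded. A
*contradictory* session is one whose two (non-zero, higher-income) pair
cases carry opposite labels; both pair-cases are removed. The accounting
report states both the number of removed pair-cases and the number of
offending sessions, since "contradictory cases" can be counted either
way; the worked accounting example (78 − 24 − 4 = 50) is consistent with
pair-case counting. The relative-income denominator is the *sum* of the
two partners' totals, with a `mean` switch (the two differ by a constant
factor and leave every correlation unchanged).

## Decomposition

Cell means Ȳ are trial-level by default; a subjects-first option (mean
of participant means per cell) matches second-level factorial practice.
The frequency weights P are pooled trial counts over the whole dataset,
renormalised over exactly the category set entering each marginal sum:
all three rules for ψ(condition), and the condition set {high, low, VoI}
for ψ(rule) — the payoff-neutral middle class carries no selfish/selfless
meaning and is omitted, though the set is a parameter. Per-session
weights are possible by passing per-session data. π = τ − ψ − ψ is
computed literally from the same floating-point values, so the identity
holds machine-exactly; empty cells raise a named error rather than
propagating NaNs.

## Inference

* Choice summaries: per-participant proportions, then mean ± s.e.m.
  across participants; participants with no qualifying trials are dropped
  with a logged warning.
* Ever-chose summaries: binary per-participant indicators; the dispersion
  reported is the binomial s.e. √(p(1−p)/n). This is one convention among
  several for a single observed proportion, and no claim is made that it
  matches any particular published ±s.e.m. for this quantity.
* t tests are Welch by default (a pooled-variance switch exists); the
  2×2 χ² is uncorrected Pearson by default with a Yates option. On the
  gender × attitude table [[6, 13], [2, 29]] the uncorrected statistic is
  5.53 (p ≈ 0.019) and the corrected one 3.74 (p ≈ 0.053); neither
  variant is claimed to be the uniquely correct test for such a table —
  both are exposed.
* Cluster bootstrap: participants are resampled with replacement and each
  replicate carries all rows of the drawn participants; percentile CIs at
  level α (default 0.05), B default 2000. Significance is reported as
  CI-exclusion of the null value. A replicate on which the statistic is
  undefined (e.g. an attitude group vanishes) is logged and redrawn, with
  a retry bound. No multiple-testing correction is applied anywhere,
  matching common practice for this kind of behavioural analysis; users
  combining many contrasts should correct externally.

## Problem sizes used in the shipped experiments

The recovery and calibration experiments in the test suite use the full
default cohort (33 participants, 18 + 6 rounds × 4 sessions) over 20
seeds; bootstrap-coverage simulation uses 500 datasets of 33 clusters × 8
observations with B = 400 replicates. These sizes give Monte-Carlo error
comfortably below the effects being checked.

## Limitations

* The synthetic cohort shows that the *pipeline* recovers what its
  generator plants; it cannot validate the behavioural or neural model
  against real participants. Passing tests demonstrate estimator
  correctness, calibration of the default conditions, and bookkeeping
  integrity — not empirical claims about brains or fairness preferences.
* The policy mixture is a hand-calibrated stand-in: it reproduces
  aggregate choice shares, not individual heterogeneity, learning, or
  strategic voting (the dictatorship control exists in the design exactly
  because strategic voting is possible).
* Affect dynamics are a two-shift latent-attitude model; real thermometer
  trajectories have richer temporal structure and anchoring effects.
* The neural outcome is generated post-subtraction with homoscedastic
  Gaussian noise; scanner drift, autocorrelation, and voxel-level
  inference are out of scope, as is any anatomical interpretation.
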