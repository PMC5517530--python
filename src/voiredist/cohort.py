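"""Synthetic cohort generator.

Emulates a repeated three-player redistribution experiment: 33 participants
each play four sessions (VoI/Informed crossed with Voting/Dictatorship).
Within a session the three income classes rotate randomly over the players
and the society-level outcome schedule guarantees that every (class,
societal outcome) pair is experienced, except in rounds the participant
decides as dictator; lottery rounds with the same screen format are randomly
inserted.  Partners are simulated confederates: their votes (or dictator
choices) enact the outcome schedule, mirroring a deception design in which
the society-level result is experimentally controlled.

On top of the behavioural stream the generator produces

* feeling-thermometer ratings (I before play, II after play, III after the
  session incomes are disclosed) driven by a latent accordance /
  non-accordance attitude per participant-partner-session pair, and
* a trial-level continuous outcome standing in for ROI percent signal
  change (redistribution minus lottery contrast already applied), from a
  linear model with a condition x decision interaction term.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .game import (
    CLASSES,
    RULES,
    Condition,
    IncomeClass,
    PayoffScheme,
    Rule,
    DEFAULT_SCHEME,
    is_equality_or_selfless,
    payoff,
    society_decision,
    total_payout,
)

__all__ = [
    "AgentPolicy",
    "AffectGenParams",
    "NeuralGenParams",
    "CohortConfig",
    "Dataset",
    "DEFAULT_POLICY_MIXTURE",
    "choice_distribution",
    "generate_cohort",
    "generate_neural",
    "session_attitude_table",
]

SESSION_TYPES = ("voting", "dictatorship")
INFO_TYPES = ("voi", "informed")
PARTNER_IDS = ("partner_1", "partner_2")


# --------------------------------------------------------------------------
# Agent choice policy
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentPolicy:
    """Softmax utility policy over the three redistribution rules.

    Utility of a rule is ``w_self * own + w_total * total - w_fair * spread``
    where ``own`` is the decider's payoff (behind the VoI: the class-average
    payoff for an expected-value agent, the minimum class payoff for a
    maximin agent), ``total`` the societal payout, and ``spread`` the
    max-min payoff gap.  Choice probabilities are softmax at the given
    temperature (money units per logit); with probability ``tremble`` the
    agent instead picks uniformly at random, a lapse rate that keeps every
    rule reachable in every condition.
    """

    w_self: float = 1.0
    w_total: float = 0.0
    w_fair: float = 0.0
    risk: str = "expected_value"  # or "maximin"
    temperature: float = 100.0
    tremble: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not (0.0 <= self.tremble <= 1.0):
            raise ValueError(f"tremble must be in [0, 1], got {self.tremble}")
        if self.risk not in ("expected_value", "maximin"):
            raise ValueError(f"unknown risk policy: {self.risk!r}")


def choice_distribution(
    policy: AgentPolicy,
    condition: Condition,
    scheme: PayoffScheme = DEFAULT_SCHEME,
) -> np.ndarray:
    """Choice probabilities over ``RULES`` for one policy in one condition."""
    condition = Condition(condition)
    utilities = np.empty(len(RULES))
    for i, rule in enumerate(RULES):
        class_payoffs = np.array([payoff(scheme, rule, cls) for cls in CLASSES])
        if condition is Condition.VOI:
            own = class_payoffs.min() if policy.risk == "maximin" else class_payoffs.mean()
        else:
            own = payoff(scheme, rule, IncomeClass(condition.value))
        spread = class_payoffs.max() - class_payoffs.min()
        utilities[i] = (
            policy.w_self * own
            + policy.w_total * total_payout(scheme, rule)
            - policy.w_fair * spread
        )
    z = utilities / policy.temperature
    z -= z.max()
    probs = np.exp(z)
    probs /= probs.sum()
    probs = (1.0 - policy.tremble) * probs + policy.tremble / len(RULES)
    return probs


# Default population mixture.  Most agents are mildly noisy payoff
# maximisers (behind the VoI the expected-value gap between rules is small,
# so their equality share is well below one half but far from zero); a
# small fairness-motivated group and a small maximin group contribute the
# informed selfless and VoI equality choices respectively.
DEFAULT_POLICY_MIXTURE: tuple[tuple[float, AgentPolicy], ...] = (
    (0.85, AgentPolicy(w_self=1.0, temperature=100.0, tremble=0.10)),
    (0.08, AgentPolicy(w_self=1.0, w_fair=0.25, temperature=100.0, tremble=0.10)),
    (0.07, AgentPolicy(w_self=1.0, risk="maximin", temperature=80.0, tremble=0.10)),
)


# --------------------------------------------------------------------------
# Generator parameter blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AffectGenParams:
    """Feeling-thermometer generator (0-100 degree scale).

    A latent attitude (accordance / non-accordance) per
    participant-partner-session pair drives opposite-signed shifts during
    play and after income disclosure: accordance pairs warm up during play
    and cool after disclosure, non-accordance pairs do the reverse.  The
    disclosure change additionally declines with relative income (slope is
    negative) but the deterministic part never contradicts the latent
    attitude's sign; with probability ``p_zero_change`` the disclosure
    leaves the rating exactly unchanged.
    """

    baseline_mean: float = 46.0
    baseline_sd: float = 12.0
    play_effect_accordance: float = 10.4
    play_effect_non_accordance: float = -13.3
    disclosure_effect_accordance: float = -15.6
    disclosure_effect_non_accordance: float = 19.6
    p_zero_change: float = 24.0 / 78.0
    # Degrees per unit relative income.  The balanced class schedule keeps
    # the relative-income spread small (sd ~ 0.02), so a slope of this size
    # moves the disclosure change by a few degrees over the observed range,
    # yielding a weak negative income-affect correlation.
    income_slope: float = -150.0
    income_slope_center: float = 0.5  # parity value of total/(sum of partners')
    noise_sd: float = 6.0
    min_disclosure_magnitude: float = 1.0
    p_accordance: float = 0.38
    attitude_correlation: float = 0.8


@dataclass(frozen=True)
class NeuralGenParams:
    """Trial-level ROI outcome model (lottery contrast already subtracted).

    y = mu + a*1[equality rule] + b*1[VoI] + c*1[equality-in-VoI or
    selfless-informed] + d*1[accordance session] + s*relative_income*
    1[equality-in-VoI] + participant random effect + Gaussian noise.
    ``c`` is the condition x decision interaction the decomposition is meant
    to recover; positive ``c`` reproduces the positive
    equality/selfless > non-equality/selfish interaction.
    """

    mu: float = 0.0
    equality_effect: float = 0.3  # a
    voi_effect: float = -0.2  # b
    interaction_effect: float = 0.5  # c
    attitude_effect: float = 0.4  # d
    income_slope: float = -0.5  # s
    random_effect_sd: float = 0.3
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.random_effect_sd < 0:
            raise ValueError("noise_sd and random_effect_sd must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full synthetic-study configuration.

    ``rounds_per_session`` counts redistribution rounds and must be a
    multiple of 9 so that the (class x societal outcome) coverage schedule
    tiles exactly; lottery rounds are extra.
    """

    n_participants: int = 33
    rounds_per_session: int = 18
    n_lottery: int = 6
    dictator_fraction: float = 1.0 / 3.0
    scheme: PayoffScheme = DEFAULT_SCHEME
    policy_mixture: tuple[tuple[float, AgentPolicy], ...] = DEFAULT_POLICY_MIXTURE
    affect: AffectGenParams = AffectGenParams()
    neural: NeuralGenParams = NeuralGenParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.rounds_per_session < 9 or self.rounds_per_session % 9 != 0:
            raise ValueError(
                "rounds_per_session must be a positive multiple of 9 so every "
                "(class, societal outcome) pair can be covered; got "
                f"{self.rounds_per_session}"
            )
        if self.n_lottery < 0:
            raise ValueError("n_lottery must be >= 0")
        if not (0.0 <= self.dictator_fraction <= 1.0):
            raise ValueError("dictator_fraction must be in [0, 1]")
        weights = [w for w, _ in self.policy_mixture]
        if not weights or abs(sum(weights) - 1.0) > 1e-9 or min(weights) < 0:
            raise ValueError("policy_mixture weights must be non-negative and sum to 1")
        if not (0.0 <= self.affect.p_zero_change <= 1.0):
            raise ValueError("p_zero_change must be in [0, 1]")
        if not (0.0 <= self.affect.p_accordance <= 1.0):
            raise ValueError("p_accordance must be in [0, 1]")
        if not (0.0 <= self.affect.attitude_correlation <= 1.0):
            raise ValueError("attitude_correlation must be in [0, 1]")


@dataclass
class Dataset:
    """The four generated (or ingested) long-format tables."""

    decisions: pd.DataFrame
    affect: pd.DataFrame
    incomes: pd.DataFrame
    neural: pd.DataFrame


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _sample_rule(probs: np.ndarray, rng: np.random.Generator) -> Rule:
    return RULES[rng.choice(len(RULES), p=probs)]


def _simulate_session(
    pid: str,
    session_type: str,
    info_type: str,
    config: CohortConfig,
    dists: dict[Condition, np.ndarray],
    rng: np.random.Generator,
) -> tuple[list[dict], float, np.ndarray]:
    """One participant-session: returns decision rows, the participant's
    session total income, and the two partners' totals."""
    scheme = config.scheme
    session_id = f"{info_type}_{session_type}"

    n_cycles = config.rounds_per_session // 9
    schedule = [
        (cls, outcome)
        for _ in range(n_cycles)
        for cls, outcome in itertools.product(CLASSES, RULES)
    ]
    rng.shuffle(schedule)

    n_rounds = config.rounds_per_session
    if session_type == "dictatorship":
        n_self = int(round(config.dictator_fraction * n_rounds))
        # Spread self-dictator rounds over distinct (class, outcome) pairs
        # so that, whenever the schedule holds several copies of a pair, at
        # least one copy survives as a society-decided round and the
        # coverage guarantee is preserved outside dictator rounds.
        by_pair: dict[tuple, list[int]] = {}
        for idx, pair in enumerate(schedule):
            by_pair.setdefault(pair, []).append(idx)
        pools = list(by_pair.values())
        for pool in pools:
            rng.shuffle(pool)
        order = rng.permutation(len(pools))
        self_rounds: set[int] = set()
        depth = 0
        while len(self_rounds) < n_self:
            for k in order:
                if len(self_rounds) >= n_self:
                    break
                pool = pools[k]
                if depth < len(pool):
                    self_rounds.add(pool[depth])
            depth += 1
    else:
        self_rounds = set()

    total_slots = n_rounds + config.n_lottery
    lottery_slots = set(
        rng.choice(total_slots, size=config.n_lottery, replace=False).tolist()
    )

    rows: list[dict] = []
    participant_total = 0.0
    partner_totals = np.zeros(2)
    decision_i = 0
    for slot in range(total_slots):
        if slot in lottery_slots:
            # Lottery with the same screen format: a class-blind pick of a
            # payoff set, then a uniformly drawn class outcome affecting
            # only the chooser.  Partners draw their own lotteries.
            chosen = _sample_rule(dists[Condition.VOI], rng)
            outcome_cls = CLASSES[rng.integers(3)]
            pay = payoff(scheme, chosen, outcome_cls)
            rows.append(
                dict(
                    participant_id=pid,
                    session_id=session_id,
                    session_type=session_type,
                    info_type=info_type,
                    round_index=slot,
                    condition=Condition.VOI.value,
                    assigned_class=outcome_cls.value,
                    chosen_rule=chosen.value,
                    society_rule=chosen.value,
                    decider="lottery",
                    payoff=pay,
                    is_lottery=True,
                )
            )
            participant_total += pay
            for j in range(2):
                p_rule = RULES[rng.integers(3)]
                partner_totals[j] += payoff(scheme, p_rule, CLASSES[rng.integers(3)])
            continue

        cls, scheduled = schedule[decision_i]
        condition = Condition.VOI if info_type == "voi" else Condition(cls.value)
        chosen = _sample_rule(dists[condition], rng)

        if session_type == "voting":
            # Confederate partners vote the scheduled outcome, so the
            # majority enacts the coverage schedule whatever the
            # participant chooses.
            society = society_decision(
                [chosen, scheduled, scheduled], "voting", rng=rng
            )
            decider = "vote"
        elif decision_i in self_rounds:
            society = society_decision([chosen], "dictatorship", dictator_index=0)
            decider = "self_dictator"
        else:
            society = scheduled
            decider = "partner_dictator"

        pay = payoff(scheme, society, cls)
        rows.append(
            dict(
                participant_id=pid,
                session_id=session_id,
                session_type=session_type,
                info_type=info_type,
                round_index=slot,
                condition=condition.value,
                assigned_class=cls.value,
                chosen_rule=chosen.value,
                society_rule=society.value,
                decider=decider,
                payoff=pay,
                is_lottery=False,
            )
        )
        participant_total += pay
        other_classes = [c for c in CLASSES if c is not cls]
        order = rng.permutation(2)
        for j in range(2):
            partner_totals[j] += payoff(scheme, society, other_classes[order[j]])
        decision_i += 1

    return rows, participant_total, partner_totals


def _generate_affect_rows(
    pid: str,
    session_id: str,
    participant_total: float,
    partner_totals: np.ndarray,
    params: AffectGenParams,
    rng: np.random.Generator,
) -> tuple[list[dict], str]:
    """Thermometer ratings for the two partners of one session; also
    returns the session-level latent attitude used by the neural model."""
    session_attitude = (
        "accordance" if rng.random() < params.p_accordance else "non_accordance"
    )
    rel_income = participant_total / partner_totals.sum()
    rows = []
    for j, partner in enumerate(PARTNER_IDS):
        if rng.random() < params.attitude_correlation:
            attitude = session_attitude
        else:
            attitude = (
                "accordance" if rng.random() < params.p_accordance else "non_accordance"
            )
        accord = attitude == "accordance"
        rating_i = float(
            np.clip(rng.normal(params.baseline_mean, params.baseline_sd), 0.0, 100.0)
        )
        play = (
            params.play_effect_accordance if accord else params.play_effect_non_accordance
        )
        rating_ii = float(
            np.clip(rating_i + play + rng.normal(0.0, params.noise_sd), 0.0, 100.0)
        )
        if rng.random() < params.p_zero_change:
            rating_iii = rating_ii
        else:
            base = (
                params.disclosure_effect_accordance
                if accord
                else params.disclosure_effect_non_accordance
            )
            systematic = base + params.income_slope * (
                rel_income - params.income_slope_center
            )
            # The latent attitude fixes the sign of the deterministic part;
            # the income slope only modulates its magnitude.
            if accord:
                systematic = min(systematic, -params.min_disclosure_magnitude)
            else:
                systematic = max(systematic, params.min_disclosure_magnitude)
            rating_iii = float(
                np.clip(
                    rating_ii + systematic + rng.normal(0.0, params.noise_sd),
                    0.0,
                    100.0,
                )
            )
        rows.append(
            dict(
                participant_id=pid,
                session_id=session_id,
                partner_id=partner,
                rating_i=rating_i,
                rating_ii=rating_ii,
                rating_iii=rating_iii,
                latent_attitude=attitude,
                session_attitude=session_attitude,
            )
        )
    return rows, session_attitude


def generate_cohort(config: CohortConfig) -> Dataset:
    """Simulate the full synthetic study.

    Deterministic given ``config.seed``: decisions, thermometer ratings,
    accumulated incomes, and trial-level neural outcomes.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([w for w, _ in config.policy_mixture])
    policies = [p for _, p in config.policy_mixture]

    # Per-policy, per-condition choice distributions (scheme is fixed).
    dist_cache = [
        {cond: choice_distribution(pol, cond, config.scheme) for cond in Condition}
        for pol in policies
    ]

    decision_rows: list[dict] = []
    affect_rows: list[dict] = []
    income_rows: list[dict] = []
    width = len(str(config.n_participants))
    for i in range(config.n_participants):
        pid = f"p{i + 1:0{width}d}"
        policy_idx = rng.choice(len(policies), p=weights)
        dists = dist_cache[policy_idx]
        for info_type in INFO_TYPES:
            for session_type in SESSION_TYPES:
                session_id = f"{info_type}_{session_type}"
                rows, ptotal, partner_totals = _simulate_session(
                    pid, session_type, info_type, config, dists, rng
                )
                decision_rows.extend(rows)
                income_rows.append(
                    dict(
                        participant_id=pid,
                        session_id=session_id,
                        participant_total=ptotal,
                        partner_1_total=float(partner_totals[0]),
                        partner_2_total=float(partner_totals[1]),
                    )
                )
                a_rows, _ = _generate_affect_rows(
                    pid, session_id, ptotal, partner_totals, config.affect, rng
                )
                affect_rows.extend(a_rows)

    decisions = pd.DataFrame(decision_rows)
    affect = pd.DataFrame(affect_rows)
    incomes = pd.DataFrame(income_rows)
    attitudes = session_attitude_table(affect, incomes)
    neural = generate_neural(decisions, attitudes, config.neural, rng)
    return Dataset(decisions=decisions, affect=affect, incomes=incomes, neural=neural)


def session_attitude_table(affect: pd.DataFrame, incomes: pd.DataFrame) -> pd.DataFrame:
    """Session-level latent attitude joined with session relative income."""
    att = affect.drop_duplicates(["participant_id", "session_id"])[
        ["participant_id", "session_id", "session_attitude"]
    ].rename(columns={"session_attitude": "attitude"})
    inc = incomes.copy()
    inc["relative_income"] = inc["participant_total"] / (
        inc["partner_1_total"] + inc["partner_2_total"]
    )
    return att.merge(
        inc[["participant_id", "session_id", "relative_income"]],
        on=["participant_id", "session_id"],
        how="left",
    )


def generate_neural(
    decisions: pd.DataFrame,
    attitudes: pd.DataFrame,
    params: NeuralGenParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One ROI outcome per non-lottery decision trial.

    ``attitudes`` must carry one row per participant-session with columns
    ``attitude`` ("accordance"/"non_accordance") and ``relative_income``.
    """
    trials = decisions.loc[~decisions["is_lottery"]].copy()
    trials = trials.merge(
        attitudes[["participant_id", "session_id", "attitude", "relative_income"]],
        on=["participant_id", "session_id"],
        how="left",
    )
    if trials["attitude"].isna().any():
        missing = trials.loc[trials["attitude"].isna(), "participant_id"].unique()
        raise ValueError(f"missing attitude/relative_income for participants {missing}")

    is_voi = (trials["condition"] == Condition.VOI.value).to_numpy()
    is_equality = (trials["chosen_rule"] == Rule.EQUALITY.value).to_numpy()
    esl = np.array(
        [
            is_equality_or_selfless(c, r)
            for c, r in zip(trials["condition"], trials["chosen_rule"])
        ]
    )
    accord = (trials["attitude"] == "accordance").to_numpy()
    rel_income = trials["relative_income"].to_numpy(dtype=float)

    pids = trials["participant_id"].to_numpy()
    unique_pids = pd.unique(pids)
    re_values = rng.normal(0.0, params.random_effect_sd, size=len(unique_pids))
    re_map = dict(zip(unique_pids, re_values))

    signal = (
        params.mu
        + params.equality_effect * is_equality
        + params.voi_effect * is_voi
        + params.interaction_effect * esl
        + params.attitude_effect * accord
        + params.income_slope * rel_income * (is_voi & is_equality)
        + np.array([re_map[p] for p in pids])
        + rng.normal(0.0, params.noise_sd, size=len(trials))
    )
    out = trials[
        ["participant_id", "session_id", "round_index", "condition", "chosen_rule"]
    ].copy()
    out["signal"] = signal
    return out.reset_index(drop=True)
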