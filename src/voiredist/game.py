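"""Redistribution-game engine.

A hypothetical three-class society (high, middle, low income) repeatedly
chooses one of three redistribution rules.  The *inequality* rule preserves
the status quo at no cost; the *intermediate* and *equality* rules transfer
income from the high to the low class, and a fixed fraction of every
transferred amount (25 % by default) is lost as a deadweight cost.  The
transfer sizes are pinned down by requiring that the equality rule produce
exactly equal after-transfer payoffs, which is only feasible when the pre-tax
incomes satisfy ``m - l == (1 - cost_rate) * (h - m)``.

Decisions are made either behind a veil of ignorance (VoI: the decider does
not know her class) or informed of the assigned class; society-level outcomes
are fixed by majority vote (random tie-break on splits) or by a dictator.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Rule",
    "Condition",
    "IncomeClass",
    "PayoffScheme",
    "DecisionRecord",
    "SchemeError",
    "OrderingError",
    "InfeasibleEqualityError",
    "RULES",
    "CONDITIONS",
    "INFORMED_CONDITIONS",
    "CLASSES",
    "build_payoff_scheme",
    "payoff",
    "payoffs",
    "transfer_amount",
    "transfer_cost",
    "total_payout",
    "society_decision",
    "SELFLESS_RULES",
    "SELFISH_RULES",
    "decision_category",
    "is_equality_or_selfless",
    "DEFAULT_SCHEME",
]


class Rule(str, enum.Enum):
    """Redistribution rule, ordered by transfer magnitude."""

    INEQUALITY = "inequality"
    INTERMEDIATE = "intermediate"
    EQUALITY = "equality"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Condition(str, enum.Enum):
    """Decision condition: VoI hides the class, the rest are Informed."""

    VOI = "voi"
    HIGH = "high"
    MIDDLE = "middle"
    LOW = "low"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class IncomeClass(str, enum.Enum):
    HIGH = "high"
    MIDDLE = "middle"
    LOW = "low"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


RULES: tuple[Rule, ...] = (Rule.INEQUALITY, Rule.INTERMEDIATE, Rule.EQUALITY)
CONDITIONS: tuple[Condition, ...] = (
    Condition.VOI,
    Condition.HIGH,
    Condition.MIDDLE,
    Condition.LOW,
)
INFORMED_CONDITIONS: tuple[Condition, ...] = (
    Condition.HIGH,
    Condition.MIDDLE,
    Condition.LOW,
)
CLASSES: tuple[IncomeClass, ...] = (
    IncomeClass.HIGH,
    IncomeClass.MIDDLE,
    IncomeClass.LOW,
)


class SchemeError(ValueError):
    """Invalid payoff-scheme parameters."""


class OrderingError(SchemeError):
    """Pre-tax incomes do not satisfy h > m > l > 0."""


class InfeasibleEqualityError(SchemeError):
    """Pre-tax incomes cannot be equalised exactly at the given cost rate.

    The equality rule takes T = h - m from the high class and delivers
    (1 - cost_rate) * T to the low class; all three payoffs coincide only
    when m - l == (1 - cost_rate) * (h - m).
    """


@dataclass(frozen=True)
class PayoffScheme:
    """Pre-tax class incomes plus the cost-bearing transfer schedule.

    Money is in abstract non-negative points.  ``transfer`` (T = h - m) is
    the amount taken from the high class under the equality rule; the
    intermediate rule transfers ``intermediate_fraction * T``.
    """

    h: float
    m: float
    l: float
    cost_rate: float = 0.25
    intermediate_fraction: float = 0.5

    @property
    def transfer(self) -> float:
        return self.h - self.m

    @property
    def endowment(self) -> float:
        return self.h + self.m + self.l

    def as_dict(self) -> dict:
        return {
            "pre_tax": {"h": self.h, "m": self.m, "l": self.l},
            "cost_rate": self.cost_rate,
            "intermediate_fraction": self.intermediate_fraction,
        }


@dataclass(frozen=True)
class DecisionRecord:
    """One round's decision context and outcome for one participant."""

    participant_id: str
    session_id: str
    session_type: str  # "voting" | "dictatorship"
    info_type: str  # "voi" | "informed"
    round_index: int
    condition: Condition
    assigned_class: IncomeClass
    chosen_rule: Rule
    society_rule: Rule
    decider: str  # "vote" | "self_dictator" | "partner_dictator" | "lottery"
    payoff: float
    is_lottery: bool = False


def build_payoff_scheme(
    h: float,
    m: float,
    l: float,
    cost_rate: float = 0.25,
    intermediate_fraction: float = 0.5,
    *,
    rtol: float = 1e-9,
) -> PayoffScheme:
    """Validate pre-tax incomes and return a :class:`PayoffScheme`.

    Raises
    ------
    OrderingError
        If ``h > m > l > 0`` fails.
    InfeasibleEqualityError
        If ``m - l != (1 - cost_rate) * (h - m)`` (beyond ``rtol``), i.e. the
        equality rule cannot flatten the payoffs exactly.
    """
    if not (h > m > l > 0):
        raise OrderingError(
            f"pre-tax incomes must satisfy h > m > l > 0; got h={h}, m={m}, l={l}"
        )
    if not (0 <= cost_rate < 1):
        raise SchemeError(f"cost_rate must be in [0, 1); got {cost_rate}")
    if not (0 < intermediate_fraction < 1):
        raise SchemeError(
            f"intermediate_fraction must be in (0, 1); got {intermediate_fraction}"
        )
    expected_gap = (1.0 - cost_rate) * (h - m)
    if not math.isclose(m - l, expected_gap, rel_tol=rtol, abs_tol=rtol * max(h, 1.0)):
        raise InfeasibleEqualityError(
            "equality-feasibility constraint violated: require "
            f"m - l == (1 - cost_rate)*(h - m), i.e. {m - l} == {expected_gap}"
        )
    return PayoffScheme(
        h=float(h),
        m=float(m),
        l=float(l),
        cost_rate=float(cost_rate),
        intermediate_fraction=float(intermediate_fraction),
    )


DEFAULT_SCHEME = PayoffScheme(h=2100.0, m=1300.0, l=700.0)


def transfer_amount(scheme: PayoffScheme, rule: Rule) -> float:
    """Amount taken from the high class under ``rule``."""
    rule = Rule(rule)
    if rule is Rule.INEQUALITY:
        return 0.0
    if rule is Rule.INTERMEDIATE:
        return scheme.intermediate_fraction * scheme.transfer
    return scheme.transfer


def transfer_cost(scheme: PayoffScheme, rule: Rule) -> float:
    """Deadweight loss of ``rule``: cost_rate times the transferred amount."""
    return scheme.cost_rate * transfer_amount(scheme, rule)


def payoff(scheme: PayoffScheme, rule: Rule, cls: IncomeClass) -> float:
    """After-transfer payoff for one income class under one rule.

    Transfers flow only high -> low; the middle-class payoff is therefore
    identical under all three rules.
    """
    cls = IncomeClass(cls)
    t = transfer_amount(scheme, rule)
    if cls is IncomeClass.HIGH:
        return scheme.h - t
    if cls is IncomeClass.MIDDLE:
        return scheme.m
    return scheme.l + (1.0 - scheme.cost_rate) * t


def payoffs(scheme: PayoffScheme, rule: Rule) -> dict[IncomeClass, float]:
    """Payoffs of all three classes under ``rule``."""
    return {cls: payoff(scheme, rule, cls) for cls in CLASSES}


def total_payout(scheme: PayoffScheme, rule: Rule) -> float:
    """Total society payoff: endowment minus the deadweight transfer cost."""
    return scheme.endowment - transfer_cost(scheme, rule)


# Class-interest groupings for the Informed conditions.  High earners lose
# from any transfer, so inequality is their selfish choice; low earners gain
# most from equality, so equality is their selfish choice; the middle class
# is unaffected by the rule and hence neutral.
SELFLESS_RULES: dict[Condition, frozenset[Rule]] = {
    Condition.HIGH: frozenset({Rule.INTERMEDIATE, Rule.EQUALITY}),
    Condition.LOW: frozenset({Rule.INEQUALITY, Rule.INTERMEDIATE}),
}
SELFISH_RULES: dict[Condition, frozenset[Rule]] = {
    Condition.HIGH: frozenset({Rule.INEQUALITY}),
    Condition.LOW: frozenset({Rule.EQUALITY}),
}


def decision_category(condition: Condition, rule: Rule) -> str:
    """Classify a decision as the behavioural analyses group them.

    Returns ``"equality"`` / ``"non_equality"`` behind the VoI,
    ``"selfless"`` / ``"selfish"`` in the informed high and low classes,
    and ``"neutral"`` in the informed middle class (every rule pays the
    middle class the same, so the choice carries no class interest).
    """
    condition = Condition(condition)
    rule = Rule(rule)
    if condition is Condition.VOI:
        return "equality" if rule is Rule.EQUALITY else "non_equality"
    if condition is Condition.MIDDLE:
        return "neutral"
    return "selfless" if rule in SELFLESS_RULES[condition] else "selfish"


def is_equality_or_selfless(condition: Condition, rule: Rule) -> bool:
    """True for VoI-equality and informed selfless decisions (the pooled
    contrast cell); False for everything else including neutral middle."""
    return decision_category(condition, rule) in ("equality", "selfless")


def society_decision(
    choices: Sequence[Rule],
    mode: str,
    dictator_index: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Rule:
    """Resolve the society-level rule from individual choices.

    Voting requires exactly three choices: a strict majority wins; a
    three-way split is decided by a uniform random draw among the cast
    votes.  Dictatorship returns the dictator's choice.
    """
    choices = [Rule(c) for c in choices]
    mode = str(mode)
    if mode == "dictatorship":
        if dictator_index is None:
            raise ValueError("dictator_index is required in dictatorship mode")
        return choices[dictator_index]
    if mode != "voting":
        raise ValueError(f"unknown decision mode: {mode!r}")
    if len(choices) != 3:
        raise ValueError(f"voting requires exactly three choices, got {len(choices)}")
    for rule in RULES:
        if choices.count(rule) >= 2:
            return rule
    if rng is None:
        rng = np.random.default_rng()
    return choices[rng.integers(len(choices))]
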