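"""Baseline-invariant decomposition of the condition x decision interaction.

In a factorial design over decision conditions (VoI, high, middle, low) and
chosen rules (inequality, intermediate, equality), the size of a naive
interaction contrast depends on which cell is treated as baseline.  The
decomposition used here removes that dependence by splitting the combined
cell contrast into average marginal effects:

    tau(c1, r1; c0, r0)  = Ybar(c1, r1) - Ybar(c0, r0)
    psi(c1; c0)          = sum_r  [Ybar(c1, r) - Ybar(c0, r)] * P(r)
    psi(r1; r0)          = sum_c  [Ybar(c, r1) - Ybar(c, r0)] * P(c)
                           (c runs over a condition set that omits the
                           payoff-neutral middle class)
    pi                   = tau - psi(condition) - psi(rule)

``Ybar`` is the mean trial outcome of a cell and ``P`` the observed choice /
condition frequency, pooled over the dataset and renormalised over exactly
the categories entering each marginal sum.  ``pi`` is the baseline-invariant
interaction: it vanishes identically for any additive table
``Ybar(c, r) = f(c) + g(r)`` and is unchanged by adding a constant to every
cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .game import CONDITIONS, RULES, Condition, Rule

__all__ = [
    "CellTable",
    "DecompositionResult",
    "EmptyCellError",
    "DEFAULT_PSI_RULE_CONDITIONS",
    "cell_means",
    "tau",
    "psi_condition",
    "psi_rule",
    "pi",
    "decompose",
]

Cell = tuple[Condition, Rule]

# The middle class is payoff-neutral across rules, so the printed marginal
# rule effect averages over the high, low, and VoI conditions only.
DEFAULT_PSI_RULE_CONDITIONS: tuple[Condition, ...] = (
    Condition.HIGH,
    Condition.LOW,
    Condition.VOI,
)


class EmptyCellError(ValueError):
    """A contrast touches a (condition, rule) cell with no trials."""

    def __init__(self, condition: Condition, rule: Rule):
        self.cell = (condition, rule)
        super().__init__(
            f"cell (condition={condition.value}, rule={rule.value}) has no trials; "
            "the requested contrast cannot be evaluated"
        )


@dataclass(frozen=True)
class CellTable:
    """Cell means and trial counts over conditions x rules.

    ``means[(condition, rule)]`` is the mean outcome of that cell (present
    only for cells with at least one trial); ``counts`` are pooled trial
    counts used as observed frequencies for the marginal weights.
    """

    means: Mapping[Cell, float]
    counts: Mapping[Cell, int]

    def mean(self, condition: Condition, rule: Rule) -> float:
        condition, rule = Condition(condition), Rule(rule)
        try:
            return self.means[(condition, rule)]
        except KeyError:
            raise EmptyCellError(condition, rule) from None

    def rule_weights(self, rules: Sequence[Rule] = RULES) -> dict[Rule, float]:
        """Observed rule-choice frequencies, normalised over ``rules``."""
        totals = {
            r: sum(n for (c, rr), n in self.counts.items() if rr is Rule(r))
            for r in rules
        }
        grand = sum(totals.values())
        if grand == 0:
            raise ValueError(f"no trials over rules {[Rule(r).value for r in rules]}")
        return {Rule(r): totals[r] / grand for r in rules}

    def condition_weights(
        self, conditions: Sequence[Condition] = DEFAULT_PSI_RULE_CONDITIONS
    ) -> dict[Condition, float]:
        """Observed condition frequencies, normalised over ``conditions``."""
        totals = {
            c: sum(n for (cc, r), n in self.counts.items() if cc is Condition(c))
            for c in conditions
        }
        grand = sum(totals.values())
        if grand == 0:
            raise ValueError(
                f"no trials over conditions {[Condition(c).value for c in conditions]}"
            )
        return {Condition(c): totals[c] / grand for c in conditions}


@dataclass(frozen=True)
class DecompositionResult:
    """tau, the two marginal psi effects, and the invariant interaction pi
    for one target/baseline cell contrast.  ``pi == tau - psi_condition -
    psi_rule`` holds exactly by construction."""

    target: Cell
    baseline: Cell
    tau: float
    psi_condition: float
    psi_rule: float
    pi: float

    def as_dict(self) -> dict:
        (c1, r1), (c0, r0) = self.target, self.baseline
        return {
            "target_condition": c1.value,
            "target_rule": r1.value,
            "baseline_condition": c0.value,
            "baseline_rule": r0.value,
            "tau": self.tau,
            "psi_condition": self.psi_condition,
            "psi_rule": self.psi_rule,
            "pi": self.pi,
        }


def cell_means(
    outcomes: pd.DataFrame,
    value_col: str = "signal",
    condition_col: str = "condition",
    rule_col: str = "rule",
    participant_col: Optional[str] = None,
) -> CellTable:
    """Aggregate per-trial outcomes into a :class:`CellTable`.

    By default cells are trial-level means.  With ``participant_col`` set,
    each cell mean is the unweighted mean of participant means (subjects
    first, as in a second-level factorial analysis); counts remain pooled
    trial counts either way, since the frequency weights P are observed
    choice frequencies.
    """
    if rule_col not in outcomes.columns and "chosen_rule" in outcomes.columns:
        rule_col = "chosen_rule"
    df = outcomes[[condition_col, rule_col, value_col]].copy()
    if participant_col is not None:
        df[participant_col] = outcomes[participant_col]

    means: dict[Cell, float] = {}
    counts: dict[Cell, int] = {}
    grouped = df.groupby([condition_col, rule_col], observed=True)
    for (cond, rule), sub in grouped:
        cell = (Condition(cond), Rule(rule))
        counts[cell] = len(sub)
        if participant_col is not None:
            means[cell] = float(
                sub.groupby(participant_col)[value_col].mean().mean()
            )
        else:
            means[cell] = float(sub[value_col].mean())
    return CellTable(means=means, counts=counts)


def tau(table: CellTable, target: Cell, baseline: Cell) -> float:
    """Average treatment combination effect: difference of two cell means."""
    (c1, r1), (c0, r0) = target, baseline
    return table.mean(c1, r1) - table.mean(c0, r0)


def psi_condition(
    table: CellTable,
    c1: Condition,
    c0: Condition,
    rules: Sequence[Rule] = RULES,
) -> float:
    """Average marginal condition effect: per-rule condition differences
    weighted by the observed rule-choice frequencies."""
    weights = table.rule_weights(rules)
    return sum(
        (table.mean(c1, r) - table.mean(c0, r)) * w for r, w in weights.items()
    )


def psi_rule(
    table: CellTable,
    r1: Rule,
    r0: Rule,
    conditions: Sequence[Condition] = DEFAULT_PSI_RULE_CONDITIONS,
) -> float:
    """Average marginal rule effect: per-condition rule differences weighted
    by the observed condition frequencies (middle omitted by default)."""
    weights = table.condition_weights(conditions)
    return sum(
        (table.mean(c, r1) - table.mean(c, r0)) * w for c, w in weights.items()
    )


def pi(
    table: CellTable,
    target: Cell,
    baseline: Cell,
    rules: Sequence[Rule] = RULES,
    conditions: Sequence[Condition] = DEFAULT_PSI_RULE_CONDITIONS,
) -> DecompositionResult:
    """Baseline-invariant interaction for the target vs baseline contrast."""
    (c1, r1), (c0, r0) = target, baseline
    c1, r1 = Condition(c1), Rule(r1)
    c0, r0 = Condition(c0), Rule(r0)
    t = tau(table, (c1, r1), (c0, r0))
    p_c = psi_condition(table, c1, c0, rules)
    p_r = psi_rule(table, r1, r0, conditions)
    return DecompositionResult(
        target=(c1, r1),
        baseline=(c0, r0),
        tau=t,
        psi_condition=p_c,
        psi_rule=p_r,
        pi=t - p_c - p_r,
    )


# The headline contrast: an equality decision behind the VoI against the
# selfish status quo of the informed high class.
DEFAULT_TARGET: Cell = (Condition.VOI, Rule.EQUALITY)
DEFAULT_BASELINE: Cell = (Condition.HIGH, Rule.INEQUALITY)


def decompose(
    outcomes: pd.DataFrame,
    target: Cell = DEFAULT_TARGET,
    baseline: Cell = DEFAULT_BASELINE,
    value_col: str = "signal",
    participant_col: Optional[str] = None,
) -> DecompositionResult:
    """Convenience wrapper: aggregate trials and decompose one contrast."""
    table = cell_means(
        outcomes, value_col=value_col, participant_col=participant_col
    )
    return pi(table, target, baseline)
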