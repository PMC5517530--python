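"""Behavioural summaries, association tests, and the participant-level
cluster bootstrap.

Choice summaries follow the convention of computing a proportion per
participant first and reporting mean +/- s.e.m. across participants.  The
bootstrap resamples whole participants (every row of a drawn participant
enters the replicate) to respect within-participant dependence of repeated
sessions and trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .game import Rule, decision_category

logger = logging.getLogger(__name__)

__all__ = [
    "ProportionSummary",
    "BootstrapResult",
    "choice_proportion_summary",
    "ever_chose_summary",
    "two_sample_t_test",
    "chi2_2x2",
    "pearson_r",
    "cluster_bootstrap",
]


@dataclass(frozen=True)
class ProportionSummary:
    """Participant-level proportions with their mean and dispersion."""

    name: str
    per_participant: pd.Series
    mean: float
    sem: float
    n: int

    def as_dict(self) -> dict:
        return {"name": self.name, "mean": self.mean, "sem": self.sem, "n": self.n}


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile cluster-bootstrap summary for one statistic."""

    name: str
    estimate: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    alpha: float
    null_value: float
    excludes_null: bool
    n_failures: int = 0

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "null_value": self.null_value,
            "excludes_null": self.excludes_null,
            "n_replicates": len(self.replicates),
            "n_failures": self.n_failures,
        }


def _resolve_rules(rule_set: str | Iterable[Rule | str], condition: str) -> set[str]:
    """Accept explicit rule collections or a named category
    ('equality_selfless' / 'non_equality_selfish') resolved per condition."""
    if isinstance(rule_set, str):
        wanted = {
            "equality_selfless": {"equality", "selfless"},
            "non_equality_selfish": {"non_equality", "selfish"},
        }[rule_set]
        return {
            r.value
            for r in Rule
            if decision_category(condition, r) in wanted
        }
    return {Rule(r).value for r in rule_set}


def _per_participant_trials(
    decisions: pd.DataFrame, condition: str
) -> pd.core.groupby.generic.DataFrameGroupBy:
    sub = decisions.loc[
        (~decisions["is_lottery"]) & (decisions["condition"] == str(condition))
    ]
    return sub.groupby("participant_id")


def choice_proportion_summary(
    decisions: pd.DataFrame,
    condition: str,
    rule_set: str | Iterable[Rule | str],
) -> ProportionSummary:
    """Proportion of non-lottery trials choosing any rule in ``rule_set``,
    per participant, summarised as mean +/- s.e.m. across participants.

    Participants with no qualifying trials in the condition are dropped
    with a warning.
    """
    rules = _resolve_rules(rule_set, condition)
    props = {}
    for pid, sub in _per_participant_trials(decisions, condition):
        if len(sub) == 0:  # pragma: no cover - groupby omits empty groups
            continue
        props[pid] = sub["chosen_rule"].isin(rules).mean()
    all_pids = decisions["participant_id"].unique()
    dropped = set(all_pids) - set(props)
    if dropped:
        logger.warning(
            "dropped %d participant(s) with no %s trials: %s",
            len(dropped),
            condition,
            sorted(dropped),
        )
    series = pd.Series(props, name="proportion").sort_index()
    n = len(series)
    mean = float(series.mean())
    sem = float(series.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    name = f"P(trial in {sorted(rules)} | {condition})"
    return ProportionSummary(name=name, per_participant=series, mean=mean, sem=sem, n=n)


def ever_chose_summary(
    decisions: pd.DataFrame,
    condition: str,
    rule_set: str | Iterable[Rule | str],
) -> ProportionSummary:
    """Proportion of participants who chose a rule in ``rule_set`` at least
    once in the condition; dispersion is the binomial s.e. sqrt(p(1-p)/n).

    Note this binomial formula is a modelling choice for a single observed
    proportion; other dispersion conventions (e.g. across sessions) exist.
    """
    rules = _resolve_rules(rule_set, condition)
    indicators = {}
    for pid, sub in _per_participant_trials(decisions, condition):
        indicators[pid] = float(sub["chosen_rule"].isin(rules).any())
    all_pids = decisions["participant_id"].unique()
    dropped = set(all_pids) - set(indicators)
    if dropped:
        logger.warning(
            "dropped %d participant(s) with no %s trials: %s",
            len(dropped),
            condition,
            sorted(dropped),
        )
    series = pd.Series(indicators, name="ever_chose").sort_index()
    n = len(series)
    p = float(series.mean())
    sem = float(np.sqrt(p * (1.0 - p) / n)) if n > 0 else 0.0
    name = f"P(ever chose {sorted(rules)} | {condition})"
    return ProportionSummary(name=name, per_participant=series, mean=p, sem=sem, n=n)


def two_sample_t_test(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-tailed two-sample t test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(
    table: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 contingency table.

    Continuity correction (Yates) is off by default; enable with
    ``correction=True``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared test undefined with a zero marginal")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cluster_bootstrap(
    data: pd.DataFrame,
    statistic_fn: Callable[[pd.DataFrame], float],
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    cluster_col: str = "participant_id",
    null_value: float = 0.0,
    name: str = "statistic",
    max_retries: int = 100,
) -> BootstrapResult:
    """Percentile bootstrap resampling whole participants with replacement.

    Each replicate draws n clusters (participants) with replacement and
    carries *all* rows of each drawn cluster, so within-participant
    dependence is preserved.  A replicate on which ``statistic_fn`` raises
    is logged and redrawn, up to ``max_retries`` extra draws in total.
    Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    clusters = pd.unique(data[cluster_col])
    n_clusters = len(clusters)
    if n_clusters < 2:
        raise ValueError("need at least two clusters to bootstrap")
    # Pre-split row indices per cluster for fast replicate assembly.
    positions = {
        cid: np.flatnonzero((data[cluster_col] == cid).to_numpy())
        for cid in clusters
    }
    estimate = float(statistic_fn(data))

    replicates = np.empty(B)
    failures = 0
    b = 0
    while b < B:
        draw = rng.integers(n_clusters, size=n_clusters)
        idx = np.concatenate([positions[clusters[i]] for i in draw])
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            replicates[b] = float(statistic_fn(sample))
        except Exception as exc:  # noqa: BLE001 - degenerate replicate
            failures += 1
            logger.info("bootstrap replicate failed (%s); redrawing", exc)
            if failures > max_retries:
                raise RuntimeError(
                    f"statistic failed on {failures} bootstrap replicates"
                ) from exc
            continue
        b += 1

    lo, hi = np.quantile(replicates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(
        name=name,
        estimate=estimate,
        replicates=replicates,
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
        null_value=null_value,
        excludes_null=bool(null_value < lo or null_value > hi),
        n_failures=failures,
    )
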