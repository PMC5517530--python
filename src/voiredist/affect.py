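"""Affective-change metrics and the accordance / non-accordance classifier.

Each participant rates each partner on a 0-100 feeling thermometer three
times per session: before play (I), after play (II), and after the session
incomes are disclosed (III).  The change during play is II - I and the
change after income disclosure is III - II.  To keep material vantage from
confounding the disclosure response, classification is restricted to cases
where the participant's total income exceeded that partner's: a *decrease*
after disclosure (unexpected from the material vantage) marks the
*accordance* attitude, an *increase* marks *non-accordance*.  Cases with
exactly zero disclosure change are excluded, as are all pair-cases of any
session in which the participant showed both attitudes to the two partners
(contradictory sessions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AffectCase",
    "ExclusionReport",
    "LABELS",
    "affective_changes",
    "relative_income",
    "classify_attitude",
    "income_side",
    "build_cases",
    "apply_exclusions",
]

LABELS = (
    "accordance",
    "non_accordance",
    "excluded_zero",
    "excluded_contradictory",
    "out_of_scope",
)


@dataclass(frozen=True)
class AffectCase:
    """One participant-partner-session thermometer triple with context."""

    participant_id: str
    session_id: str
    partner_id: str
    rating_i: float
    rating_ii: float
    rating_iii: float
    participant_total: float
    partner_total: float

    @property
    def delta_play(self) -> float:
        return self.rating_ii - self.rating_i

    @property
    def delta_disclosure(self) -> float:
        return self.rating_iii - self.rating_ii


@dataclass
class ExclusionReport:
    """Filter accounting for the attitude classification.

    ``n_contradictory_cases`` counts the pair-cases removed;
    ``n_contradictory_sessions`` the participant-sessions responsible (the
    printed accounting is consistent with pair-case counting, but both
    readings are reported).
    """

    n_total: int = 0
    n_out_of_scope: int = 0
    n_higher_income: int = 0
    n_zero_change: int = 0
    n_contradictory_cases: int = 0
    n_contradictory_sessions: int = 0
    n_retained: int = 0
    n_accordance: int = 0
    n_non_accordance: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def to_text(self) -> str:
        lines = [
            "Attitude classification accounting",
            f"  all cases:                    {self.n_total}",
            f"  out of scope (not higher):    {self.n_out_of_scope}",
            f"  higher-income cases:          {self.n_higher_income}",
            f"  excluded, zero change:        {self.n_zero_change}",
            f"  excluded, contradictory:      {self.n_contradictory_cases}"
            f" (from {self.n_contradictory_sessions} sessions)",
            f"  retained:                     {self.n_retained}",
            f"    accordance:                 {self.n_accordance}",
            f"    non-accordance:             {self.n_non_accordance}",
        ]
        return "\n".join(lines)


def _check_rating(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"{name} must lie in [0, 100] degrees, got {value}")
    return value


def affective_changes(
    rating_i: float, rating_ii: float, rating_iii: float
) -> tuple[float, float]:
    """(change during play II - I, change after income disclosure III - II)."""
    i = _check_rating(rating_i, "rating_i")
    ii = _check_rating(rating_ii, "rating_ii")
    iii = _check_rating(rating_iii, "rating_iii")
    return ii - i, iii - ii


def relative_income(
    participant_total: float,
    partner_totals: Sequence[float],
    denominator: str = "sum",
) -> float:
    """Participant's total income divided by the partners' total income.

    The partners' income is their summed total by default (``"mean"``
    rescales by the number of partners; correlations are unaffected).
    """
    totals = np.asarray(partner_totals, dtype=float)
    if participant_total < 0 or (totals < 0).any():
        raise ValueError("total incomes must be non-negative")
    denom = totals.sum()
    if denominator == "mean":
        denom /= len(totals)
    elif denominator != "sum":
        raise ValueError(f"denominator must be 'sum' or 'mean', got {denominator!r}")
    if denom <= 0:
        raise ZeroDivisionError("partners' total income must be positive")
    return float(participant_total) / float(denom)


def income_side(participant_total: float, partner_total: float) -> str:
    """Which side of that partner's total the participant's total falls on."""
    if participant_total > partner_total:
        return "higher"
    if participant_total < partner_total:
        return "lower"
    return "equal"


def classify_attitude(delta_disclosure: float, side: str) -> str:
    """Label one case by its disclosure response.

    Only higher-income cases are in scope; among them a decrease is
    *accordance*, an increase *non-accordance*, and exactly zero change is
    excluded.
    """
    if side != "higher":
        return "out_of_scope"
    if delta_disclosure < 0:
        return "accordance"
    if delta_disclosure > 0:
        return "non_accordance"
    return "excluded_zero"


def build_cases(
    affect: pd.DataFrame,
    incomes: pd.DataFrame,
    denominator: str = "sum",
) -> pd.DataFrame:
    """Join thermometer rows with session incomes into labelled cases.

    Returns one row per participant-partner-session with the two affective
    changes, the per-partner income side, the session relative income, and
    the pre-exclusion attitude label.
    """
    inc = incomes.copy()
    inc["partners_total"] = inc["partner_1_total"] + inc["partner_2_total"]
    cases = affect.merge(inc, on=["participant_id", "session_id"], how="left")
    if cases["participant_total"].isna().any():
        bad = cases.loc[
            cases["participant_total"].isna(), ["participant_id", "session_id"]
        ].drop_duplicates()
        raise ValueError(f"no income row for sessions:\n{bad}")
    partner_total = np.where(
        cases["partner_id"] == "partner_1",
        cases["partner_1_total"],
        cases["partner_2_total"],
    )
    cases["partner_total"] = partner_total
    cases["delta_play"] = cases["rating_ii"] - cases["rating_i"]
    cases["delta_disclosure"] = cases["rating_iii"] - cases["rating_ii"]
    cases["relative_income"] = [
        relative_income(pt, (p1, p2), denominator=denominator)
        for pt, p1, p2 in zip(
            cases["participant_total"],
            cases["partner_1_total"],
            cases["partner_2_total"],
        )
    ]
    cases["income_side"] = [
        income_side(pt, qt)
        for pt, qt in zip(cases["participant_total"], cases["partner_total"])
    ]
    cases["label"] = [
        classify_attitude(d, s)
        for d, s in zip(cases["delta_disclosure"], cases["income_side"])
    ]
    keep = [
        "participant_id",
        "session_id",
        "partner_id",
        "rating_i",
        "rating_ii",
        "rating_iii",
        "delta_play",
        "delta_disclosure",
        "participant_total",
        "partner_total",
        "relative_income",
        "income_side",
        "label",
    ]
    extra = [c for c in ("latent_attitude", "session_attitude") if c in cases.columns]
    return cases[keep + extra]


def apply_exclusions(cases: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop zero-change and contradictory cases; account for every filter.

    ``cases`` must carry ``label`` as produced by :func:`build_cases` (or
    :func:`classify_attitude`).  Contradictory sessions are
    participant-sessions whose higher-income, non-zero cases carry both
    attitude labels; *all* their pair-cases are removed.
    """
    report = ExclusionReport(n_total=len(cases))
    report.n_out_of_scope = int((cases["label"] == "out_of_scope").sum())
    in_scope = cases.loc[cases["label"] != "out_of_scope"].copy()
    report.n_higher_income = len(in_scope)

    zero_mask = in_scope["label"] == "excluded_zero"
    report.n_zero_change = int(zero_mask.sum())
    for _, row in in_scope.loc[zero_mask].iterrows():
        logger.info(
            "excluded (zero disclosure change): %s / %s / %s",
            row["participant_id"],
            row["session_id"],
            row["partner_id"],
        )
    nonzero = in_scope.loc[~zero_mask].copy()

    label_counts = nonzero.groupby(["participant_id", "session_id"])["label"].nunique()
    contradictory_sessions = label_counts[label_counts > 1].index
    report.n_contradictory_sessions = len(contradictory_sessions)
    session_key = pd.MultiIndex.from_frame(nonzero[["participant_id", "session_id"]])
    contra_mask = session_key.isin(contradictory_sessions)
    report.n_contradictory_cases = int(contra_mask.sum())
    for _, row in nonzero.loc[contra_mask].iterrows():
        logger.info(
            "excluded (contradictory session): %s / %s / %s",
            row["participant_id"],
            row["session_id"],
            row["partner_id"],
        )
    retained = nonzero.loc[~contra_mask].copy()
    contra = nonzero.loc[contra_mask].copy()
    contra["label"] = "excluded_contradictory"

    report.n_retained = len(retained)
    report.n_accordance = int((retained["label"] == "accordance").sum())
    report.n_non_accordance = int((retained["label"] == "non_accordance").sum())
    assert (
        report.n_retained + report.n_zero_change + report.n_contradictory_cases
        == report.n_higher_income
    )
    return retained.reset_index(drop=True), report
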