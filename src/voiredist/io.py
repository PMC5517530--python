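"""Table schemas, run configuration, and the end-to-end pipeline.

Interchange format is plain CSV with a header row; every file written by the
pipeline starts with a ``# config_hash=...`` comment so outputs are
traceable to the exact configuration.  ``RunConfig`` is validated strictly
(unknown keys are rejected) before any stage runs.

A BIDS-style events.tsv maps onto decisions.csv as: onset/duration are not
modelled; trial_type corresponds to (condition, chosen_rule, is_lottery);
response fields correspond to chosen_rule; participant/session identifiers
map to participant_id/session_id.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _pkg_version
from .affect import ExclusionReport, apply_exclusions, build_cases
from .cohort import (
    AffectGenParams,
    AgentPolicy,
    CohortConfig,
    Dataset,
    NeuralGenParams,
    generate_cohort,
    session_attitude_table,
)
from .decomposition import DecompositionResult, cell_means, pi
from .game import (
    CONDITIONS,
    RULES,
    Condition,
    Rule,
    build_payoff_scheme,
)
from .inference import (
    BootstrapResult,
    choice_proportion_summary,
    cluster_bootstrap,
    ever_chose_summary,
    pearson_r,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SchemaError",
    "PipelineResult",
    "read_config",
    "read_tables",
    "write_tables",
    "run_pipeline",
]

_RULE_VALUES = {r.value for r in Rule}
_CONDITION_VALUES = {c.value for c in Condition}
_SESSION_IDS = {
    "voi_voting",
    "voi_dictatorship",
    "informed_voting",
    "informed_dictatorship",
}


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PayoffBlock(_StrictModel):
    h: float = 2100.0
    m: float = 1300.0
    l: float = 700.0
    cost_rate: float = 0.25
    intermediate_fraction: float = 0.5


class PolicyBlock(_StrictModel):
    weight: float
    w_self: float = 1.0
    w_total: float = 0.0
    w_fair: float = 0.0
    risk: Literal["expected_value", "maximin"] = "expected_value"
    temperature: float = 100.0
    tremble: float = 0.0


_DEFAULT_MIXTURE = [
    PolicyBlock(weight=0.85, w_self=1.0, temperature=100.0, tremble=0.10),
    PolicyBlock(weight=0.08, w_self=1.0, w_fair=0.25, temperature=100.0, tremble=0.10),
    PolicyBlock(weight=0.07, w_self=1.0, risk="maximin", temperature=80.0, tremble=0.10),
]


class CohortBlock(_StrictModel):
    n_participants: int = 33
    rounds_per_session: int = 18
    n_lottery: int = 6
    dictator_fraction: float = 1.0 / 3.0
    policy_mixture: list[PolicyBlock] = Field(
        default_factory=lambda: list(_DEFAULT_MIXTURE)
    )


class AffectBlock(_StrictModel):
    baseline_mean: float = 46.0
    baseline_sd: float = 12.0
    play_effect_accordance: float = 10.4
    play_effect_non_accordance: float = -13.3
    disclosure_effect_accordance: float = -15.6
    disclosure_effect_non_accordance: float = 19.6
    p_zero_change: float = 24.0 / 78.0
    income_slope: float = -150.0
    income_slope_center: float = 0.5
    noise_sd: float = 6.0
    min_disclosure_magnitude: float = 1.0
    p_accordance: float = 0.38
    attitude_correlation: float = 0.8


class NeuralBlock(_StrictModel):
    mu: float = 0.0
    equality_effect: float = 0.3
    voi_effect: float = -0.2
    interaction_effect: float = 0.5
    attitude_effect: float = 0.4
    income_slope: float = -0.5
    random_effect_sd: float = 0.3
    noise_sd: float = 1.0


class ContrastBlock(_StrictModel):
    condition: Literal["voi", "high", "middle", "low"]
    rule: Literal["inequality", "intermediate", "equality"]


class AnalysisBlock(_StrictModel):
    bootstrap_b: int = 2000
    alpha: float = 0.05
    equal_var: bool = False
    chi2_correction: bool = False
    per_participant_cells: bool = False
    relative_income_denominator: Literal["sum", "mean"] = "sum"
    target: ContrastBlock = ContrastBlock(condition="voi", rule="equality")
    baseline: ContrastBlock = ContrastBlock(condition="high", rule="inequality")


class RunConfig(_StrictModel):
    """Validated run configuration for the whole pipeline."""

    seed: int = 0
    payoff: PayoffBlock = PayoffBlock()
    cohort: CohortBlock = CohortBlock()
    affect: AffectBlock = AffectBlock()
    neural: NeuralBlock = NeuralBlock()
    analysis: AnalysisBlock = AnalysisBlock()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_cohort_config(self) -> CohortConfig:
        scheme = build_payoff_scheme(
            self.payoff.h,
            self.payoff.m,
            self.payoff.l,
            self.payoff.cost_rate,
            self.payoff.intermediate_fraction,
        )
        mixture = tuple(
            (
                p.weight,
                AgentPolicy(
                    w_self=p.w_self,
                    w_total=p.w_total,
                    w_fair=p.w_fair,
                    risk=p.risk,
                    temperature=p.temperature,
                    tremble=p.tremble,
                ),
            )
            for p in self.cohort.policy_mixture
        )
        affect = AffectGenParams(**self.affect.model_dump())
        neural = NeuralGenParams(**self.neural.model_dump())
        return CohortConfig(
            n_participants=self.cohort.n_participants,
            rounds_per_session=self.cohort.rounds_per_session,
            n_lottery=self.cohort.n_lottery,
            dictator_fraction=self.cohort.dictator_fraction,
            scheme=scheme,
            policy_mixture=mixture,
            affect=affect,
            neural=neural,
            seed=self.seed,
        )


def read_config(path: str | Path | None = None, seed: Optional[int] = None) -> RunConfig:
    """Load a YAML run config (defaults when ``path`` is None); ``seed``
    overrides the file's seed."""
    if path is None:
        cfg = RunConfig()
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = RunConfig.model_validate(raw)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    return cfg


# --------------------------------------------------------------------------
# Table IO and validation
# --------------------------------------------------------------------------

class SchemaError(ValueError):
    """CSV content violates the documented schema."""

    def __init__(self, file: str, row: object, column: str, message: str):
        self.file, self.row, self.column = file, row, column
        super().__init__(f"{file} (row {row}, column {column!r}): {message}")


TABLE_SCHEMAS: dict[str, list[str]] = {
    "decisions": [
        "participant_id",
        "session_id",
        "session_type",
        "info_type",
        "round_index",
        "condition",
        "assigned_class",
        "chosen_rule",
        "society_rule",
        "decider",
        "payoff",
        "is_lottery",
    ],
    "affect": [
        "participant_id",
        "session_id",
        "partner_id",
        "rating_i",
        "rating_ii",
        "rating_iii",
    ],
    "incomes": [
        "participant_id",
        "session_id",
        "participant_total",
        "partner_1_total",
        "partner_2_total",
    ],
    "neural": [
        "participant_id",
        "session_id",
        "round_index",
        "condition",
        "chosen_rule",
        "signal",
    ],
}


def _check_categorical(df: pd.DataFrame, file: str, column: str, allowed: set) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            file, row, column, f"value {df[column].iloc[row]!r} not in {sorted(allowed)}"
        )


def _check_range(
    df: pd.DataFrame, file: str, column: str, low: float, high: float
) -> None:
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna() | (vals < low) | (vals > high)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            file, row, column, f"value {df[column].iloc[row]!r} outside [{low}, {high}]"
        )


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_tables(directory: str | Path) -> Dataset:
    """Read and validate the four pipeline tables from ``directory``.

    Checks required columns, categorical codes, rating/money ranges, and
    referential integrity (every affect/incomes/neural participant must
    appear in decisions).  Raises :class:`SchemaError` naming file, row,
    and column on the first violation.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, columns in TABLE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table: {path}")
        df = _read_csv(path)
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(path.name, "header", missing[0], "column missing")
        frames[name] = df

    dec = frames["decisions"]
    f = "decisions.csv"
    _check_categorical(dec, f, "session_id", _SESSION_IDS)
    _check_categorical(dec, f, "session_type", {"voting", "dictatorship"})
    _check_categorical(dec, f, "info_type", {"voi", "informed"})
    _check_categorical(dec, f, "condition", _CONDITION_VALUES)
    _check_categorical(dec, f, "assigned_class", {"high", "middle", "low"})
    _check_categorical(dec, f, "chosen_rule", _RULE_VALUES)
    _check_categorical(dec, f, "society_rule", _RULE_VALUES)
    _check_categorical(
        dec, f, "decider", {"vote", "self_dictator", "partner_dictator", "lottery"}
    )
    _check_range(dec, f, "payoff", 0.0, np.inf)

    aff = frames["affect"]
    for col in ("rating_i", "rating_ii", "rating_iii"):
        _check_range(aff, "affect.csv", col, 0.0, 100.0)

    inc = frames["incomes"]
    for col in ("participant_total", "partner_1_total", "partner_2_total"):
        _check_range(inc, "incomes.csv", col, 0.0, np.inf)

    _check_range(frames["neural"], "neural.csv", "signal", -np.inf, np.inf)

    known = set(dec["participant_id"])
    for name in ("affect", "incomes", "neural"):
        other = frames[name]
        bad = ~other["participant_id"].isin(known)
        if bad.any():
            row = int(other.index[bad][0])
            raise SchemaError(
                f"{name}.csv",
                row,
                "participant_id",
                f"participant {other['participant_id'].iloc[row]!r} "
                "does not appear in decisions.csv",
            )
    return Dataset(
        decisions=dec, affect=aff, incomes=inc, neural=frames["neural"]
    )


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def write_tables(dataset: Dataset, directory: str | Path, config_hash: str = "") -> None:
    """Write the four tables as CSV (with a config-hash comment line)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in TABLE_SCHEMAS:
        _write_csv(getattr(dataset, name), directory / f"{name}.csv", config_hash)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: RunConfig
    config_hash: str
    dataset: Dataset
    cases: pd.DataFrame
    retained: pd.DataFrame
    exclusions: ExclusionReport
    behavior: pd.DataFrame
    decomposition: DecompositionResult
    income_affect_r: tuple[float, float]
    bootstraps: dict[str, BootstrapResult]
    out_dir: Optional[Path] = None


def _behavior_table(decisions: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for condition in ("voi", "high", "low"):
        for rule_set in ("equality_selfless", "non_equality_selfish"):
            prop = choice_proportion_summary(decisions, condition, rule_set)
            ever = ever_chose_summary(decisions, condition, rule_set)
            rows.append(
                dict(
                    condition=condition,
                    rule_set=rule_set,
                    trial_mean=prop.mean,
                    trial_sem=prop.sem,
                    ever_mean=ever.mean,
                    ever_sem=ever.sem,
                    n_participants=prop.n,
                )
            )
    return pd.DataFrame(rows)


def _attitude_signal_gap(neural_with_attitude: pd.DataFrame) -> float:
    """Mean ROI signal on equality/selfless trials, accordance minus
    non-accordance sessions."""
    sub = neural_with_attitude.loc[neural_with_attitude["esl"]]
    acc = sub.loc[sub["attitude"] == "accordance", "signal"]
    non = sub.loc[sub["attitude"] == "non_accordance", "signal"]
    if len(acc) == 0 or len(non) == 0:
        raise ValueError("a replicate lost one attitude group entirely")
    return float(acc.mean() - non.mean())


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    dataset: Optional[Dataset] = None,
) -> PipelineResult:
    """Simulate (or ingest) data and run every analysis stage.

    Stages: synthetic cohort -> affect classification with exclusion
    accounting -> behavioural summaries -> interaction decomposition ->
    clustered bootstraps.  Deterministic given the config seed.
    """
    from .game import is_equality_or_selfless  # local import to avoid cycle noise

    config_hash = config.config_hash()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setLevel(logging.INFO)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root = logging.getLogger("voiredist")
        prev_level = root.level
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    else:
        handler = None

    try:
        logger.info(
            "pipeline start: seed=%d config_hash=%s voiredist=%s python=%s "
            "numpy=%s pandas=%s",
            config.seed,
            config_hash,
            _pkg_version,
            platform.python_version(),
            np.__version__,
            pd.__version__,
        )
        if dataset is None:
            logger.info("stage simulate")
            dataset = generate_cohort(config.to_cohort_config())

        logger.info("stage affect_metrics")
        try:
            cases = build_cases(
                dataset.affect,
                dataset.incomes,
                denominator=config.analysis.relative_income_denominator,
            )
            retained, exclusions = apply_exclusions(cases)
        except Exception as exc:
            raise RuntimeError(f"stage affect_metrics failed: {exc}") from exc

        logger.info("stage behavior")
        try:
            behavior = _behavior_table(dataset.decisions)
        except Exception as exc:
            raise RuntimeError(f"stage behavior failed: {exc}") from exc

        logger.info("stage decomposition")
        target = (
            Condition(config.analysis.target.condition),
            Rule(config.analysis.target.rule),
        )
        baseline = (
            Condition(config.analysis.baseline.condition),
            Rule(config.analysis.baseline.rule),
        )
        try:
            table = cell_means(
                dataset.neural,
                value_col="signal",
                participant_col=(
                    "participant_id" if config.analysis.per_participant_cells else None
                ),
            )
            decomposition = pi(table, target, baseline)
        except Exception as exc:
            raise RuntimeError(
                f"stage decomposition failed: {exc} "
                "(hint: with few trials or extreme policies a cell can be "
                "empty; increase rounds_per_session or choose a different "
                "contrast)"
            ) from exc

        logger.info("stage inference")
        try:
            r, p = pearson_r(retained["relative_income"], retained["delta_disclosure"])
        except Exception as exc:
            raise RuntimeError(f"stage inference failed: {exc}") from exc

        logger.info("stage bootstrap")
        attitudes = session_attitude_table(dataset.affect, dataset.incomes)
        neural_att = dataset.neural.merge(
            attitudes, on=["participant_id", "session_id"], how="left"
        )
        neural_att["esl"] = [
            is_equality_or_selfless(c, rle)
            for c, rle in zip(neural_att["condition"], neural_att["chosen_rule"])
        ]
        boot_seed = np.random.default_rng(config.seed + 1)
        try:
            bootstraps = {
                "attitude_signal_gap": cluster_bootstrap(
                    neural_att,
                    _attitude_signal_gap,
                    B=config.analysis.bootstrap_b,
                    seed=boot_seed,
                    alpha=config.analysis.alpha,
                    null_value=0.0,
                    name="attitude_signal_gap",
                ),
                "income_affect_r": cluster_bootstrap(
                    retained,
                    lambda df: pearson_r(
                        df["relative_income"], df["delta_disclosure"]
                    )[0],
                    B=config.analysis.bootstrap_b,
                    seed=boot_seed,
                    alpha=config.analysis.alpha,
                    null_value=0.0,
                    name="income_affect_r",
                ),
            }
        except Exception as exc:
            raise RuntimeError(f"stage bootstrap failed: {exc}") from exc

        result = PipelineResult(
            config=config,
            config_hash=config_hash,
            dataset=dataset,
            cases=cases,
            retained=retained,
            exclusions=exclusions,
            behavior=behavior,
            decomposition=decomposition,
            income_affect_r=(r, p),
            bootstraps=bootstraps,
            out_dir=out_dir,
        )
        if out_dir is not None:
            _write_outputs(result, out_dir)
        logger.info("pipeline done")
        return result
    finally:
        if handler is not None:
            logging.getLogger("voiredist").removeHandler(handler)
            logging.getLogger("voiredist").setLevel(prev_level)
            handler.close()


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    h = result.config_hash
    write_tables(result.dataset, out_dir, h)
    _write_csv(result.cases, out_dir / "attitudes.csv", h)
    _write_csv(result.behavior, out_dir / "behavior.csv", h)
    _write_csv(
        pd.DataFrame([result.decomposition.as_dict()]), out_dir / "decomposition.csv", h
    )
    with open(out_dir / "exclusions.json", "w") as fh:
        json.dump(
            {"config_hash": h, **result.exclusions.as_dict()}, fh, indent=2
        )
    with open(out_dir / "config.yaml", "w") as fh:
        fh.write(f"# config_hash={h}\n")
        yaml.safe_dump(result.config.model_dump(), fh, sort_keys=False)
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(format_report(result))


def format_report(result: PipelineResult) -> str:
    """Human-readable summary of one pipeline run."""
    lines = [
        f"voiredist pipeline report (config {result.config_hash}, "
        f"seed {result.config.seed})",
        "",
        result.exclusions.to_text(),
        "",
        "Behavioural summaries (mean +/- sem across participants):",
    ]
    for _, row in result.behavior.iterrows():
        lines.append(
            f"  {row['condition']:>5} {row['rule_set']:<22} "
            f"trials {100 * row['trial_mean']:5.1f}% +/- {100 * row['trial_sem']:4.1f}%   "
            f"ever {100 * row['ever_mean']:5.1f}% +/- {100 * row['ever_sem']:4.1f}%"
        )
    d = result.decomposition
    (c1, r1), (c0, r0) = d.target, d.baseline
    r, p = result.income_affect_r
    lines += [
        "",
        f"Interaction decomposition pi({c1.value},{r1.value}; {c0.value},{r0.value}):",
        f"  tau = {d.tau:.4f}  psi_condition = {d.psi_condition:.4f}  "
        f"psi_rule = {d.psi_rule:.4f}  pi = {d.pi:.4f}",
        "",
        f"Relative income vs disclosure change: r = {r:.3f} (p = {p:.3g})",
        "",
        "Cluster bootstraps (percentile CI):",
    ]
    for b in result.bootstraps.values():
        lines.append(
            f"  {b.name}: {b.estimate:.4f} "
            f"[{b.ci_low:.4f}, {b.ci_high:.4f}] "
            f"(alpha={b.alpha}, excludes {b.null_value}: {b.excludes_null})"
        )
    return "\n".join(lines) + "\n"
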