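"""Sequential trial execution: Dunnett statistics, stage decisions, operating
characteristics.

The statistic comparing arm k with the shared control at stage j is the
many-to-one z statistic

    Z_kj = (mean_control - mean_k) / (sigma * sqrt(1/n_0j + 1/n_kj)),

with variance treated as known. The primary endpoint improves by decreasing,
so larger Z means more effective. Statistics for different arms share the
control group and are correlated (0.5 under equal allocation) — the
generalized Dunnett structure. Decision rules per stage: Z below the futility
bound drops the arm, Z above the efficacy bound declares it effective,
otherwise it continues; the final stage leaves no continue verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .design import (
    BoundarySet,
    CalibratedDesign,
    _cumulative_z,
    _sequential_outcomes,
)
from .errors import ConfigurationError, DataExhaustedError, InvalidParameterError

__all__ = [
    "GroupSummary",
    "Verdict",
    "StageDecision",
    "TrialResult",
    "OCReport",
    "dunnett_statistic",
    "interim_decision",
    "run_trial",
    "operating_characteristics",
]

CONTROL = "control"


@dataclass(frozen=True)
class GroupSummary:
    """Cumulative sample size and mean outcome for one arm at one look."""

    label: str
    n: int
    mean: float


class Verdict(str, Enum):
    CONTINUE = "continue"
    DROP_FUTILE = "drop-futile"
    DECLARE_EFFECTIVE = "declare-effective"


@dataclass(frozen=True)
class StageDecision:
    """Per-arm statistics and verdicts at one interim analysis."""

    stage: int  # 1-based
    statistics: Mapping[str, float]
    verdicts: Mapping[str, Verdict]
    active_after: frozenset[str]


@dataclass(frozen=True)
class TrialResult:
    decisions: tuple[StageDecision, ...]
    effective: Mapping[str, int]  # arm -> 1-based stage of the efficacy claim
    total_subjects: int


@dataclass(frozen=True)
class OCReport:
    """Monte Carlo operating characteristics of a calibrated design under a
    configured scenario of true per-arm effects."""

    fwer: float
    fwer_se: float
    power: float
    power_se: float
    rejection_probs: Mapping[str, float]
    rejection_ses: Mapping[str, float]
    expected_n: float
    expected_n_se: float
    max_planned_n: int
    stop_stage_dist: Mapping[str, np.ndarray]
    reps: int
    seed: int

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "arm": arm,
                "rejection_prob": self.rejection_probs[arm],
                "rejection_se": self.rejection_ses[arm],
                **{
                    f"p_stop_stage_{j + 1}": p
                    for j, p in enumerate(self.stop_stage_dist[arm])
                },
            }
            for arm in self.rejection_probs
        ]
        return pd.DataFrame(rows)


def dunnett_statistic(control: GroupSummary, arm: GroupSummary, sigma: float) -> float:
    """Many-to-one z statistic; positive when the arm mean is below control."""
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    if control.n < 1 or arm.n < 1:
        raise InvalidParameterError("group sizes must be at least 1")
    se = sigma * math.sqrt(1.0 / control.n + 1.0 / arm.n)
    return (control.mean - arm.mean) / se


def interim_decision(
    stats: Mapping[str, float],
    bounds: BoundarySet,
    stage: int,
    active: Sequence[str] | frozenset[str],
    final_stage: bool | None = None,
) -> StageDecision:
    """Apply the stage decision rule to each active arm's statistic.

    ``stage`` is 1-based. Exact boundary ties resolve to continue (a
    measure-zero event, fixed for determinism); at the final stage the closed
    triangle leaves ties as the only non-verdict, and they count as futile.
    """
    if not 1 <= stage <= bounds.n_stages:
        raise ConfigurationError(
            f"no boundary defined for stage {stage} (design has {bounds.n_stages})"
        )
    active = frozenset(active)
    missing = set(stats) - active
    if missing:
        raise ConfigurationError(f"statistics supplied for inactive arms: {sorted(missing)}")
    if final_stage is None:
        final_stage = stage == bounds.n_stages
    u = bounds.upper[stage - 1]
    lo = bounds.lower[stage - 1]
    verdicts: dict[str, Verdict] = {}
    for arm, z in stats.items():
        if z > u:
            verdicts[arm] = Verdict.DECLARE_EFFECTIVE
        elif z < lo or final_stage:
            verdicts[arm] = Verdict.DROP_FUTILE
        else:
            verdicts[arm] = Verdict.CONTINUE
    still_active = frozenset(a for a, v in verdicts.items() if v is Verdict.CONTINUE)
    return StageDecision(
        stage=stage, statistics=dict(stats), verdicts=verdicts, active_after=still_active
    )


def run_trial(
    design: CalibratedDesign,
    outcomes: Mapping[str, Sequence[float]],
) -> TrialResult:
    """Execute one whole trial on fixed outcome streams.

    ``outcomes`` maps each arm label (plus ``"control"``) to its ordered
    outcome stream. Stages are processed in order; an arm dropped for
    futility or declared effective stops consuming subjects, and the control
    keeps recruiting while any arm remains active. Deterministic given its
    inputs.
    """
    if CONTROL not in outcomes:
        raise ConfigurationError("outcome streams must include a 'control' entry")
    arms = [a for a in outcomes if a != CONTROL]
    if not arms:
        raise ConfigurationError("no intervention arms in outcome streams")
    streams = {a: np.asarray(v, dtype=float) for a, v in outcomes.items()}
    n_per_stage = design.n_per_stage
    sigma = design.spec.sigma

    active = list(arms)
    consumed = dict.fromkeys(streams, 0)
    decisions: list[StageDecision] = []
    effective: dict[str, int] = {}
    for j, n_j in enumerate(n_per_stage, start=1):
        for label in [CONTROL, *active]:
            if len(streams[label]) < n_j:
                raise DataExhaustedError(
                    f"arm '{label}' supplies {len(streams[label])} outcomes but "
                    f"stage {j} needs {n_j}"
                )
            consumed[label] = n_j
        ctrl = GroupSummary(CONTROL, n_j, float(streams[CONTROL][:n_j].mean()))
        stats = {
            a: dunnett_statistic(ctrl, GroupSummary(a, n_j, float(streams[a][:n_j].mean())), sigma)
            for a in active
        }
        decision = interim_decision(stats, design.boundaries, j, active)
        decisions.append(decision)
        for arm, v in decision.verdicts.items():
            if v is Verdict.DECLARE_EFFECTIVE:
                effective[arm] = j
        active = [a for a in active if a in decision.active_after]
        if not active:
            break
    total = sum(consumed.values())
    return TrialResult(tuple(decisions), effective, total)


def operating_characteristics(
    design: CalibratedDesign,
    scenario: Mapping[str, float],
    reps: int = 10_000,
    seed: int = 0,
) -> OCReport:
    """Estimate operating characteristics under per-arm true mean decreases.

    ``scenario`` maps each intervention arm label to its true decrease from
    the control mean (positive = beneficial). FWER counts an efficacy claim
    on any arm whose true decrease is <= 0 (a true null); power is the
    probability that every arm with a decrease at or above the design's
    interesting effect is declared effective (NaN if the scenario contains
    none). Sufficient-statistic simulation: group means are drawn directly,
    no subject-level loop.
    """
    if reps < 1000:
        raise InvalidParameterError("reps must be at least 1000")
    arms = list(scenario)
    if len(arms) != design.spec.n_arms:
        raise InvalidParameterError(
            f"scenario assigns {len(arms)} arms but the design has {design.spec.n_arms}"
        )
    decreases = np.asarray([scenario[a] for a in arms], dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((reps, len(arms) + 1, design.spec.n_stages))
    z = _cumulative_z(eps, design.n_per_stage, decreases, design.spec.sigma)
    effective, stop_stage = _sequential_outcomes(
        z, design.boundaries.upper, design.boundaries.lower
    )

    null_true = decreases <= 0
    eff_true = decreases >= design.spec.effects().delta - 1e-12
    fwer = float(effective[:, null_true].any(axis=1).mean()) if null_true.any() else 0.0
    power = float(effective[:, eff_true].all(axis=1).mean()) if eff_true.any() else float("nan")

    n_cum = design.n_per_stage.astype(float)
    arm_n = n_cum[stop_stage]  # (reps, K): subjects per arm at its stop stage
    control_n = n_cum[stop_stage.max(axis=1)]  # control recruits while trial runs
    total_n = arm_n.sum(axis=1) + control_n

    se = 1.0 / math.sqrt(reps)
    rej = effective.mean(axis=0)
    dist = {
        arm: np.bincount(stop_stage[:, k], minlength=design.spec.n_stages) / reps
        for k, arm in enumerate(arms)
    }
    return OCReport(
        fwer=fwer,
        fwer_se=math.sqrt(fwer * (1 - fwer)) * se,
        power=power,
        power_se=(math.sqrt(power * (1 - power)) * se if not math.isnan(power) else float("nan")),
        rejection_probs={arm: float(rej[k]) for k, arm in enumerate(arms)},
        rejection_ses={
            arm: math.sqrt(rej[k] * (1 - rej[k])) * se for k, arm in enumerate(arms)
        },
        expected_n=float(total_n.mean()),
        expected_n_se=float(total_n.std(ddof=1) * se),
        max_planned_n=design.total_planned_n,
        stop_stage_dist=dist,
        reps=reps,
        seed=seed,
    )
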