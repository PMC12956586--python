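"""Synthetic subject-level cohorts with the statistical structure the design
assumes.

Each subject carries a stratum (laboratory x sex x animal model), an assigned
arm, disposition milestones (randomized, surgery, dosing) and a day-30
outcome. Outcomes are independent normal draws around the arm mean (control
mean minus the arm's true decrease, plus an optional per-laboratory shift)
with known s.d.; deaths are Bernoulli with the configured attrition rate,
occur on a uniform day in 1..30, and remove the day-30 outcome (missing
completely at random). Dosing follows the intraperitoneal schedule of one
dose at surgery and twice daily through day 3 (six doses in total) unless a
different prescription is configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CalibratedDesign
from .errors import DataExhaustedError, InvalidParameterError

__all__ = ["ScenarioSpec", "generate_cohort", "stage_stream", "COHORT_COLUMNS"]

DEFAULT_LABS = ("lab_a", "lab_b", "lab_c", "lab_d", "lab_e", "lab_f")
DEFAULT_SEXES = ("female", "male")
DEFAULT_MODELS = (
    "young_mouse",
    "aging_mouse",
    "obese_mouse",
    "young_rat",
    "hypertensive_rat",
)
# six doses: at surgery (day 0), then twice daily for five more
DOSE_DAYS = (0, 1, 1, 2, 2, 3)

COHORT_COLUMNS = [
    "subject_id",
    "laboratory",
    "sex",
    "model",
    "arm",
    "randomized",
    "surgery_completed",
    "first_dose",
    "doses_prescribed",
    "doses_given",
    "survival_day",
    "outcome_day30",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """True state of the world generating one cohort.

    ``arm_effects`` maps arm labels to true mean decreases from the control
    mean (the control arm itself has decrease 0 and must be present under the
    label ``"control"`` when streams for a trial are needed). ``n_per_cell``
    is the enrollment per arm in every laboratory x sex x model cell.
    ``lab_shifts`` adds an optional per-laboratory mean shift (between-site
    heterogeneity, default none: the conservative design keeps that
    variability inside sigma).
    """

    arm_effects: Mapping[str, float]
    control_mean: float = 0.55
    sigma: float = 1.048
    attrition_rate: float = 0.10
    n_per_cell: int = 1
    labs: Sequence[str] = DEFAULT_LABS
    sexes: Sequence[str] = DEFAULT_SEXES
    models: Sequence[str] = DEFAULT_MODELS
    lab_shifts: Mapping[str, float] = field(default_factory=dict)
    doses_prescribed: int = 6

    def __post_init__(self) -> None:
        if not self.arm_effects:
            raise InvalidParameterError("arm_effects must name at least one arm")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be nonnegative")
        if not 0 <= self.attrition_rate < 1:
            raise InvalidParameterError("attrition_rate must be in [0,1)")
        if self.n_per_cell < 0:
            raise InvalidParameterError("n_per_cell must be nonnegative")
        unknown = set(self.lab_shifts) - set(self.labs)
        if unknown:
            raise InvalidParameterError(f"lab_shifts for unknown labs: {sorted(unknown)}")

    @property
    def strata(self) -> list[tuple[str, str, str]]:
        return [(l, s, m) for l in self.labs for s in self.sexes for m in self.models]


def generate_cohort(scenario: ScenarioSpec, seed: int) -> pd.DataFrame:
    """Draw one subject-level cohort, reproducibly for a given seed.

    Every stratum cell receives exactly ``n_per_cell`` subjects per arm, in a
    fixed enumeration order (labs x sexes x models x arms), so stratum counts
    are exact by construction and the output is byte-identical for identical
    seeds.
    """
    rng = np.random.default_rng(seed)
    arms = list(scenario.arm_effects)
    strata = scenario.strata
    n = scenario.n_per_cell * len(strata) * len(arms)

    lab = np.repeat([s[0] for s in strata], len(arms) * scenario.n_per_cell)
    sex = np.repeat([s[1] for s in strata], len(arms) * scenario.n_per_cell)
    model = np.repeat([s[2] for s in strata], len(arms) * scenario.n_per_cell)
    arm = np.tile(np.repeat(arms, scenario.n_per_cell), len(strata))

    decrease = np.asarray([scenario.arm_effects[a] for a in arm])
    shift = np.asarray([scenario.lab_shifts.get(l, 0.0) for l in lab])
    mean = scenario.control_mean - decrease + shift
    outcome = rng.normal(mean, scenario.sigma)

    died = rng.random(n) < scenario.attrition_rate
    death_day = rng.integers(1, 31, size=n)
    survival_day = np.where(died, death_day.astype(float), np.inf)
    outcome = np.where(survival_day > 30, outcome, np.nan)

    prescribed = scenario.doses_prescribed
    dose_days = np.asarray(DOSE_DAYS[:prescribed] if prescribed <= len(DOSE_DAYS)
                           else DOSE_DAYS + tuple(range(4, 4 + prescribed - len(DOSE_DAYS))))
    # a dose scheduled on day d is given iff the subject is alive on day d
    doses_given = (dose_days[None, :] < np.where(died, death_day, 31)[:, None]).sum(axis=1)

    return pd.DataFrame(
        {
            "subject_id": [f"s{i:06d}" for i in range(n)],
            "laboratory": lab,
            "sex": sex,
            "model": model,
            "arm": arm,
            "randomized": True,
            "surgery_completed": True,
            "first_dose": doses_given > 0,
            "doses_prescribed": prescribed,
            "doses_given": doses_given,
            "survival_day": survival_day,
            "outcome_day30": outcome,
        },
        columns=COHORT_COLUMNS,
    )


def stage_stream(cohort: pd.DataFrame, design: CalibratedDesign) -> dict[str, np.ndarray]:
    """Adapt a cohort table into per-arm outcome streams for trial execution.

    Survivors' day-30 outcomes are ordered by enrollment (row order within
    the cohort); dead subjects contribute nothing. Raises if any arm cannot
    supply the design's maximum cumulative group size.
    """
    if len(cohort) == 0:
        raise DataExhaustedError("cohort is empty")
    need = design.n_final
    streams: dict[str, np.ndarray] = {}
    for arm, grp in cohort.groupby("arm", sort=False):
        vals = grp["outcome_day30"].dropna().to_numpy(dtype=float)
        if len(vals) < need:
            raise DataExhaustedError(
                f"arm '{arm}' has {len(vals)} day-30 outcomes but the design "
                f"needs up to {need}"
            )
        streams[str(arm)] = vals
    return streams
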