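"""Stratified block randomization, balance/medication audits and CONSORT
analysis-population classification.

Randomization is stratified by laboratory, sex and animal model: each stratum
cell owns its own sequence of permuted blocks, and subjects are assigned to
the next available (lowest-index unconsumed) row of their stratum's table,
mirroring how a coordinating center serves assignments. Block sizes are a
multiple of the number of arms so every completed block is exactly balanced.

The CONSORT populations are nested: intention-to-treat (ITT) = everything
randomized; modified ITT = ITT subjects who completed the disease-model
surgery and began dosing; per-protocol (PP) = mITT subjects who received
every prescribed dose and survived at least 5 days after surgery.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, DataIntegrityError, InvalidParameterError

__all__ = [
    "RandTable",
    "build_randomization_table",
    "default_block_size",
    "audit_balance",
    "classify_populations",
    "medication_error_audit",
]

STRATUM_COLS = ["laboratory", "sex", "model"]


def default_block_size(n_arms: int, weekly_enrollment: int = 8) -> int:
    """Smallest multiple of the number of arms at or above weekly enrollment."""
    if n_arms < 1 or weekly_enrollment < 1:
        raise InvalidParameterError("n_arms and weekly_enrollment must be positive")
    return n_arms * math.ceil(weekly_enrollment / n_arms)


class RandTable:
    """An ordered stratified block-randomization table with consumption state.

    Wraps a DataFrame with columns ``row, laboratory, sex, model, block,
    block_size, arm, consumed``; ``assign_next`` serves and marks the lowest
    unconsumed row of a stratum, so consumed rows are always a prefix within
    each stratum.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"row", *STRATUM_COLS, "block", "block_size", "arm", "consumed"}
        missing = required - set(frame.columns)
        if missing:
            raise InvalidParameterError(f"randomization table missing columns: {sorted(missing)}")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def assign_next(self, stratum: tuple[str, str, str]) -> pd.Series:
        """Return and consume the next available row for a stratum."""
        lab, sex, model = stratum
        f = self._frame
        mask = (
            (f["laboratory"] == lab)
            & (f["sex"] == sex)
            & (f["model"] == model)
            & ~f["consumed"]
        )
        idx = mask.idxmax() if mask.any() else None
        if idx is None:
            raise CapacityError(f"stratum {stratum} has no unconsumed rows left")
        self._frame.loc[idx, "consumed"] = True
        return self._frame.loc[idx]

    def consumed_rows(self) -> pd.DataFrame:
        return self._frame[self._frame["consumed"]]

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RandTable":
        return cls(pd.read_csv(path))


def build_randomization_table(
    arms: Sequence[str],
    strata: Sequence[tuple[str, str, str]],
    block_size: int,
    n_blocks: int,
    seed: int,
) -> RandTable:
    """Build permuted-block assignment rows for every stratum cell.

    Within each block every arm appears exactly ``block_size / len(arms)``
    times in uniformly random order; blocks are generated stratum by stratum
    in the given order, deterministically for a given seed.
    """
    arms = list(arms)
    if len(set(arms)) != len(arms) or not arms:
        raise InvalidParameterError("arms must be a non-empty list of unique labels")
    if n_blocks < 1:
        raise InvalidParameterError("n_blocks must be >= 1")
    if block_size % len(arms) != 0:
        raise InvalidParameterError(
            f"block_size {block_size} is not divisible by {len(arms)} arms"
        )
    reps = block_size // len(arms)
    rng = np.random.default_rng(seed)
    records = []
    row = 0
    for stratum in strata:
        lab, sex, model = stratum
        for b in range(n_blocks):
            order = rng.permutation(np.repeat(arms, reps))
            for arm in order:
                records.append(
                    {
                        "row": row,
                        "laboratory": lab,
                        "sex": sex,
                        "model": model,
                        "block": b,
                        "block_size": block_size,
                        "arm": arm,
                        "consumed": False,
                    }
                )
                row += 1
    return RandTable(pd.DataFrame.from_records(records))


def audit_balance(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum arm-count spread (max - min) over consumed assignments.

    Zero whenever consumption ends on a block boundary; otherwise bounded by
    ``block_size * (arms - 1) / arms``.
    """
    if len(assignments) == 0:
        return pd.DataFrame(columns=[*STRATUM_COLS, "imbalance"])
    counts = (
        assignments.groupby([*STRATUM_COLS, "arm"], sort=True).size().unstack(fill_value=0)
    )
    imbalance = counts.max(axis=1) - counts.min(axis=1)
    out = imbalance.rename("imbalance").reset_index()
    return out


def classify_populations(cohort: pd.DataFrame) -> pd.DataFrame:
    """Flag each subject's CONSORT analysis populations (ITT / mITT / PP).

    Raises when disposition milestones are inconsistent (dosing without
    surgery, or surgery without randomization). The returned flags are nested
    by construction: PP implies mITT implies ITT.
    """
    required = {
        "subject_id",
        "randomized",
        "surgery_completed",
        "first_dose",
        "doses_prescribed",
        "doses_given",
        "survival_day",
    }
    missing = required - set(cohort.columns)
    if missing:
        raise DataIntegrityError(f"cohort missing disposition columns: {sorted(missing)}")
    randomized = cohort["randomized"].astype(bool)
    surgery = cohort["surgery_completed"].astype(bool)
    first_dose = cohort["first_dose"].astype(bool)
    if (surgery & ~randomized).any():
        raise DataIntegrityError("surgery recorded for non-randomized subjects")
    if (first_dose & ~surgery).any():
        raise DataIntegrityError("dosing recorded before disease-model surgery")
    if ((cohort["doses_given"] > 0) != first_dose).any():
        raise DataIntegrityError("doses_given inconsistent with first_dose flag")

    itt = randomized
    mitt = itt & surgery & first_dose
    pp = (
        mitt
        & (cohort["doses_given"] >= cohort["doses_prescribed"])
        & (cohort["survival_day"] >= 5)
    )
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "in_itt": itt,
            "in_mitt": mitt,
            "in_pp": pp,
        }
    )


def medication_error_audit(
    assignments: pd.DataFrame,
    administrations: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Post hoc confirmation that each subject got its assigned intervention.

    Both tables are keyed by ``subject_id`` and carry ``arm`` and ``route``
    columns. An error is any administered intervention or route differing
    from the assignment; counts are reported by assigned route. A subject
    administered but never randomized is a referential-integrity failure.
    """
    for name, frame in (("assignments", assignments), ("administrations", administrations)):
        missing = {"subject_id", "arm", "route"} - set(frame.columns)
        if missing:
            raise DataIntegrityError(f"{name} missing columns: {sorted(missing)}")
    unknown = set(administrations["subject_id"]) - set(assignments["subject_id"])
    if unknown:
        raise DataIntegrityError(
            f"administrations for subjects never randomized: {sorted(unknown)[:5]}"
        )
    merged = administrations.merge(
        assignments, on="subject_id", suffixes=("_given", "_assigned")
    )
    mismatch = (merged["arm_given"] != merged["arm_assigned"]) | (
        merged["route_given"] != merged["route_assigned"]
    )
    errors = merged.loc[
        mismatch,
        ["subject_id", "arm_assigned", "route_assigned", "arm_given", "route_given"],
    ].reset_index(drop=True)
    counts = (
        merged.loc[mismatch].groupby("route_assigned").size()
        .reindex(sorted(assignments["route"].unique()), fill_value=0)
        .rename("errors")
    )
    return errors, counts
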