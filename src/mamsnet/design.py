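"""Multi-arm multi-stage (MAMS) design representation and calibration.

A MAMS trial compares K intervention arms against one shared control over J
sequential stages. At each interim analysis a many-to-one (Dunnett-type)
z statistic is computed for every active arm; arms falling below a futility
boundary are dropped, arms exceeding an efficacy boundary are declared
effective, and the rest continue. The stopping boundaries used here are
*triangular*: on the (score statistic, information) plane the efficacy line
is ``a + c*I`` and the futility line is ``-a + 3*c*I``; the two lines meet at
``I = a/c`` (score value ``2a``), closing the continuation region.

Because discrete-look triangular designs have no closed-form constants, the
boundary scale and the per-stage group sizes are calibrated by Monte Carlo
simulation: the boundary scale is tuned so the familywise error rate (FWER,
the probability of any false efficacy claim under the global null) equals the
target ``alpha``, and the group size is the smallest one giving the target
power under the least favorable configuration (one arm at the interesting
effect ``delta``, the others at the uninteresting effect ``delta0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError, InvalidParameterError

__all__ = [
    "DesignSpec",
    "EffectPair",
    "BoundarySet",
    "CalibratedDesign",
    "derive_effect_sizes",
    "triangular_boundaries",
    "calibrate_design",
    "adjust_for_attrition",
]

# Calibration tolerances: absolute Monte Carlo tolerance on FWER/power and
# the bisection resolution on the boundary scale parameter.
FWER_TOL = 0.005
THETA_XTOL = 1e-7
MAX_GROUP_SIZE = 1 << 20


@dataclass(frozen=True)
class DesignSpec:
    """All parameters defining one MAMS trial design.

    Defaults are the drug trial of the motivating preclinical network:
    five intervention arms plus a pooled control, four stages with interim
    analyses after 25/50/75% of recruitment, normal outcomes with known
    s.d. 1.048 around a control mean of 0.55, an interesting effect of a 50%
    decrease, an uninteresting effect of a 6% decrease, FWER 5%, power 90%,
    and 10% attrition over the 30-day follow-up.
    """

    n_arms: int = 5
    n_stages: int = 4
    interim_fractions: tuple[float, ...] = (0.25, 0.50, 0.75, 1.0)
    alpha: float = 0.05
    power_target: float = 0.90
    control_mean: float = 0.55
    sigma: float = 1.048
    eff_pct: float = 0.50
    fut_pct: float = 0.06
    attrition_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.n_arms < 1 or self.n_stages < 1:
            raise InvalidParameterError("need at least one arm and one stage")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.power_target < 1:
            raise InvalidParameterError("power_target must be in (0,1)")
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")
        if self.control_mean <= 0:
            raise InvalidParameterError("control_mean must be positive")
        if not 0 <= self.fut_pct < self.eff_pct <= 1:
            raise InvalidParameterError(
                "need 0 <= fut_pct < eff_pct <= 1, got "
                f"fut_pct={self.fut_pct}, eff_pct={self.eff_pct}"
            )
        if not 0 <= self.attrition_rate < 1:
            raise InvalidParameterError("attrition_rate must be in [0,1)")
        f = np.asarray(self.interim_fractions, dtype=float)
        if len(f) != self.n_stages:
            raise InvalidParameterError("interim_fractions must have one entry per stage")
        if np.any(np.diff(f) <= 0) or f[0] <= 0 or not math.isclose(f[-1], 1.0):
            raise InvalidParameterError(
                "interim_fractions must be strictly increasing and end at 1"
            )

    def effects(self) -> "EffectPair":
        return derive_effect_sizes(self.control_mean, self.sigma, self.eff_pct, self.fut_pct)


@dataclass(frozen=True)
class EffectPair:
    """Interesting / uninteresting effect sizes, absolute and standardized."""

    delta: float
    delta0: float
    delta_std: float
    delta0_std: float


@dataclass(frozen=True)
class BoundarySet:
    """Triangular stopping boundaries on the score and z scales.

    ``score_a`` and ``score_c`` are the triangle intercept and slope on the
    score scale; ``info`` holds the per-stage information levels I_j, and
    ``upper``/``lower`` the per-stage efficacy/futility bounds on the z scale
    (``u_j = e(I_j)/sqrt(I_j)``, ``l_j = f(I_j)/sqrt(I_j)``). When futility is
    disabled the lower bounds before the final stage are ``-inf``.
    """

    score_a: float
    score_c: float
    info: np.ndarray
    upper: np.ndarray
    lower: np.ndarray

    @property
    def n_stages(self) -> int:
        return len(self.info)

    @property
    def apex_information(self) -> float:
        return self.score_a / self.score_c


def derive_effect_sizes(
    mu0: float, sigma: float, eff_pct: float, fut_pct: float
) -> EffectPair:
    """Turn relative decreases into absolute and standardized effect sizes.

    The interesting effect is ``delta = mu0 * eff_pct`` (a decrease of at
    least ``eff_pct`` of the control mean declares an arm effective), the
    uninteresting effect ``delta0 = mu0 * fut_pct``; both are standardized by
    the known outcome s.d.
    """
    if mu0 <= 0 or sigma <= 0:
        raise InvalidParameterError("mu0 and sigma must be positive")
    if not 0 <= fut_pct < eff_pct <= 1:
        raise InvalidParameterError("need 0 <= fut_pct < eff_pct <= 1")
    delta = mu0 * eff_pct
    delta0 = mu0 * fut_pct
    return EffectPair(delta, delta0, delta / sigma, delta0 / sigma)


def triangular_boundaries(
    a: float,
    c: float,
    info_levels,
    futility: bool = True,
) -> BoundarySet:
    """Build triangular boundaries at the given information levels.

    Score-scale efficacy line ``e(I) = a + c*I`` and futility line
    ``f(I) = -a + 3*c*I`` intersect at ``I = a/c`` (common score ``2a``).
    Any information level beyond the apex is clamped to it so the triangle
    closes; the final-stage bounds always satisfy ``u_J >= l_J`` and equal
    each other when the last level reaches the apex.
    """
    if a <= 0 or c <= 0:
        raise InvalidParameterError("triangle parameters a and c must be positive")
    info = np.asarray(info_levels, dtype=float).copy()
    if info.ndim != 1 or len(info) == 0:
        raise InvalidParameterError("info_levels must be a non-empty 1-d sequence")
    if np.any(info <= 0) or np.any(np.diff(info) <= 0):
        raise InvalidParameterError("info_levels must be positive and increasing")
    apex = a / c
    info = np.minimum(info, apex)
    upper = (a + c * info) / np.sqrt(info)
    lower = (-a + 3.0 * c * info) / np.sqrt(info)
    if not futility:
        lower = lower.copy()
        lower[:-1] = -np.inf
        lower[-1] = upper[-1] if math.isclose(info[-1], apex) else lower[-1]
    return BoundarySet(score_a=a, score_c=c, info=info, upper=upper, lower=lower)


def adjust_for_attrition(n: int, rate: float) -> int:
    """Inflate a planned count for expected attrition: ceil(n / (1 - rate))."""
    if not 0 <= rate < 1:
        raise InvalidParameterError("attrition rate must be in [0, 1)")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    # tiny slack guards against float rounding when n/(1-rate) is an integer
    return int(math.ceil(n / (1.0 - rate) - 1e-9))


@dataclass(frozen=True)
class CalibratedDesign:
    """A DesignSpec with calibrated boundaries, group sizes and attained OCs.

    ``n_per_stage`` holds the cumulative per-arm group sizes n_j (the pooled
    control recruits the same n_j). ``total_planned_n`` is the maximum number
    of subjects if no arm stops early; ``total_inflated_n`` additionally
    inflates for the design's attrition rate.
    """

    spec: DesignSpec
    boundaries: BoundarySet
    n_per_stage: np.ndarray
    attained_fwer: float
    fwer_se: float
    attained_power: float
    power_se: float
    mc_reps: int
    seed: int
    futility: bool = True

    @property
    def n_final(self) -> int:
        return int(self.n_per_stage[-1])

    @property
    def total_planned_n(self) -> int:
        return (self.spec.n_arms + 1) * self.n_final

    @property
    def total_inflated_n(self) -> int:
        if self.spec.attrition_rate == 0:
            return self.total_planned_n
        return adjust_for_attrition(self.total_planned_n, self.spec.attrition_rate)

    def stage_table(self):
        """Flat per-stage table: stage, n per arm, information, bounds."""
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": np.arange(1, self.boundaries.n_stages + 1),
                "n_per_arm": self.n_per_stage,
                "information": self.boundaries.info,
                "upper": self.boundaries.upper,
                "lower": self.boundaries.lower,
            }
        )

    def metadata(self) -> dict:
        return {
            "spec": {
                "n_arms": self.spec.n_arms,
                "n_stages": self.spec.n_stages,
                "interim_fractions": list(self.spec.interim_fractions),
                "alpha": self.spec.alpha,
                "power_target": self.spec.power_target,
                "control_mean": self.spec.control_mean,
                "sigma": self.spec.sigma,
                "eff_pct": self.spec.eff_pct,
                "fut_pct": self.spec.fut_pct,
                "attrition_rate": self.spec.attrition_rate,
            },
            "score_a": float(self.boundaries.score_a),
            "score_c": float(self.boundaries.score_c),
            "attained_fwer": self.attained_fwer,
            "fwer_se": self.fwer_se,
            "attained_power": self.attained_power,
            "power_se": self.power_se,
            "mc_reps": self.mc_reps,
            "seed": self.seed,
            "futility": self.futility,
            "total_planned_n": self.total_planned_n,
            "total_inflated_n": self.total_inflated_n,
        }

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.stage_table().to_csv(d / "stages.csv", index=False)
        (d / "design.json").write_text(json.dumps(self.metadata(), indent=2))

    @classmethod
    def load(cls, directory) -> "CalibratedDesign":
        import json
        from pathlib import Path

        import pandas as pd

        d = Path(directory)
        meta = json.loads((d / "design.json").read_text())
        stages = pd.read_csv(d / "stages.csv")
        spec = DesignSpec(
            **{**meta["spec"], "interim_fractions": tuple(meta["spec"]["interim_fractions"])}
        )
        bounds = BoundarySet(
            score_a=meta["score_a"],
            score_c=meta["score_c"],
            info=stages["information"].to_numpy(),
            upper=stages["upper"].to_numpy(),
            lower=stages["lower"].to_numpy(),
        )
        return cls(
            spec=spec,
            boundaries=bounds,
            n_per_stage=stages["n_per_arm"].to_numpy(dtype=int),
            attained_fwer=meta["attained_fwer"],
            fwer_se=meta["fwer_se"],
            attained_power=meta["attained_power"],
            power_se=meta["power_se"],
            mc_reps=meta["mc_reps"],
            seed=meta["seed"],
            futility=meta["futility"],
        )


# ---------------------------------------------------------------------------
# Calibration internals
# ---------------------------------------------------------------------------

def _stage_sizes(n_final: int, fractions: np.ndarray) -> np.ndarray:
    """Cumulative per-arm group sizes at each look: ceil(f_j * n_final)."""
    n = np.ceil(fractions * n_final - 1e-9).astype(int)
    n = np.maximum.accumulate(np.maximum(n, 1))
    n[-1] = n_final
    return n


def _zbounds_from_theta(theta: float, frac: np.ndarray, futility: bool):
    """z-scale triangular bounds with apex at final information.

    With ``a = c * I_J`` and ``theta = c * sqrt(I_J)`` the z-scale bounds
    depend only on theta and the information fractions f_j = I_j / I_J:
    ``u_j = theta (1 + f_j)/sqrt(f_j)``, ``l_j = theta (3 f_j - 1)/sqrt(f_j)``.
    """
    sq = np.sqrt(frac)
    upper = theta * (1.0 + frac) / sq
    lower = theta * (3.0 * frac - 1.0) / sq
    if not futility:
        lower = lower.copy()
        lower[:-1] = -np.inf
        lower[-1] = upper[-1]
    return upper, lower


def _cumulative_z(eps: np.ndarray, n_stages_sizes: np.ndarray, decreases: np.ndarray,
                  sigma: float) -> np.ndarray:
    """Dunnett z statistics at every look from standard-normal increments.

    ``eps`` has shape (reps, K+1, J): group 0 is the shared control. Returns
    z of shape (reps, K, J) with sign convention larger z = larger decrease
    from control (more effective).
    """
    m = np.diff(n_stages_sizes, prepend=0).astype(float)  # per-stage increments
    # per-group per-stage sums of outcomes around the group mean
    sums = sigma * np.sqrt(m) * eps
    means = np.cumsum(sums, axis=2) / n_stages_sizes.astype(float)
    # add group means: control 0, arm k at -decrease_k (mu0 cancels in z)
    means[:, 1:, :] -= decreases[None, :, None]
    se = sigma * np.sqrt(2.0 / n_stages_sizes.astype(float))
    return (means[:, :1, :] - means[:, 1:, :]) / se


def _sequential_outcomes(z: np.ndarray, upper: np.ndarray, lower: np.ndarray):
    """Apply the stage decision rules to pre-computed statistics.

    Arms interact only through the shared control (already baked into z), so
    each arm's sequential path is independent: it stops at the first stage
    where z exits (l_j, u_j), effective if it exited above. Final-stage
    bounds close the region, so unstopped paths (exact boundary ties) are
    counted as not effective. Returns (effective, stop_stage) of shape
    (reps, K); stop stages are 0-based.
    """
    hit_eff = z > upper
    hit_fut = z < lower
    stopped = hit_eff | hit_fut
    any_stop = stopped.any(axis=2)
    first = np.argmax(stopped, axis=2)
    last = z.shape[2] - 1
    stop_stage = np.where(any_stop, first, last)
    effective = (
        np.take_along_axis(hit_eff, stop_stage[:, :, None], axis=2)[:, :, 0] & any_stop
    )
    return effective, stop_stage


def _fwer_on_draws(z_null: np.ndarray, frac: np.ndarray, theta: float,
                   futility: bool) -> float:
    upper, lower = _zbounds_from_theta(theta, frac, futility)
    effective, _ = _sequential_outcomes(z_null, upper, lower)
    return float(effective.any(axis=1).mean())


def _calibrate_theta(z_null: np.ndarray, frac: np.ndarray, alpha: float,
                     futility: bool) -> float:
    """Bisect the boundary scale so simulated FWER equals alpha."""
    lo, hi = 0.0, 10.0
    f_lo = _fwer_on_draws(z_null, frac, lo, futility)
    f_hi = _fwer_on_draws(z_null, frac, hi, futility)
    if f_lo < alpha - FWER_TOL or f_hi > alpha + FWER_TOL:
        raise CalibrationError(
            f"cannot bracket boundary scale: FWER({lo})={f_lo:.4f}, "
            f"FWER({hi})={f_hi:.4f}, target {alpha}"
        )
    while hi - lo > THETA_XTOL:
        mid = 0.5 * (lo + hi)
        if _fwer_on_draws(z_null, frac, mid, futility) > alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_design(
    spec: DesignSpec,
    mc_reps: int = 100_000,
    seed: int = 0,
    futility: bool = True,
) -> CalibratedDesign:
    """Calibrate triangular boundaries and group sizes by Monte Carlo search.

    Two-level deterministic search with common random numbers: for a
    candidate per-arm final group size ``n`` the boundary scale is bisected
    so the simulated FWER under the global null equals ``spec.alpha``
    (futility stops binding when ``futility=True``); the smallest ``n`` whose
    recalibrated design attains ``spec.power_target`` under the least
    favorable configuration is selected by bracketing and integer bisection.
    Identical (spec, mc_reps, seed) always yields the identical design.
    """
    if mc_reps < 1000:
        raise InvalidParameterError("mc_reps must be at least 1000")
    K, J = spec.n_arms, spec.n_stages
    frac_planned = np.asarray(spec.interim_fractions, dtype=float)
    eff = spec.effects()

    rng = np.random.default_rng(seed)
    eps_null = rng.standard_normal((mc_reps, K + 1, J))
    eps_lfc = rng.standard_normal((mc_reps, K + 1, J))
    zero = np.zeros(K)
    lfc = np.full(K, eff.delta0)
    lfc[0] = eff.delta

    cache: dict[int, tuple] = {}

    def evaluate(n_final: int):
        if n_final in cache:
            return cache[n_final]
        n_stages_sizes = _stage_sizes(n_final, frac_planned)
        frac = n_stages_sizes / n_stages_sizes[-1]
        z_null = _cumulative_z(eps_null, n_stages_sizes, zero, spec.sigma)
        theta = _calibrate_theta(z_null, frac, spec.alpha, futility)
        fwer = _fwer_on_draws(z_null, frac, theta, futility)
        upper, lower = _zbounds_from_theta(theta, frac, futility)
        z_alt = _cumulative_z(eps_lfc, n_stages_sizes, lfc, spec.sigma)
        effective, _ = _sequential_outcomes(z_alt, upper, lower)
        power = float(effective[:, 0].mean())
        cache[n_final] = (theta, fwer, power, n_stages_sizes)
        return cache[n_final]

    # bracket: start from the single-arm fixed-sample size, double until the
    # target power is reached
    from scipy.stats import norm

    z_a, z_b = norm.ppf(1 - spec.alpha), norm.ppf(spec.power_target)
    n_lo = max(J, int(2.0 * ((z_a + z_b) / eff.delta_std) ** 2 * 0.5))
    while evaluate(n_lo)[2] >= spec.power_target and n_lo > J:
        n_lo = max(J, n_lo // 2)
        if n_lo == J:
            break
    n_hi = max(2 * n_lo, n_lo + 1)
    while evaluate(n_hi)[2] < spec.power_target:
        n_lo = n_hi
        n_hi *= 2
        if n_hi > MAX_GROUP_SIZE:
            raise CalibrationError(
                f"no group size below {MAX_GROUP_SIZE} attains power "
                f"{spec.power_target} (last estimate {evaluate(n_lo)[2]:.4f})"
            )
    if evaluate(n_lo)[2] >= spec.power_target:
        n_hi = n_lo
    # integer bisection for the smallest adequate n
    while n_hi - n_lo > 1:
        mid = (n_lo + n_hi) // 2
        if evaluate(mid)[2] >= spec.power_target:
            n_hi = mid
        else:
            n_lo = mid
    theta, fwer, power, n_stages_sizes = evaluate(n_hi)

    # recover score-scale triangle constants from theta and final information
    info = n_stages_sizes / (2.0 * spec.sigma**2)
    c = theta / math.sqrt(info[-1])
    a = theta * math.sqrt(info[-1])
    upper, lower = _zbounds_from_theta(theta, n_stages_sizes / n_stages_sizes[-1], futility)
    bounds = BoundarySet(score_a=a, score_c=c, info=info, upper=upper, lower=lower)

    se = 1.0 / math.sqrt(mc_reps)
    return CalibratedDesign(
        spec=spec,
        boundaries=bounds,
        n_per_stage=n_stages_sizes,
        attained_fwer=fwer,
        fwer_se=math.sqrt(fwer * (1 - fwer)) * se,
        attained_power=power,
        power_se=math.sqrt(power * (1 - power)) * se,
        mc_reps=mc_reps,
        seed=seed,
        futility=futility,
    )
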