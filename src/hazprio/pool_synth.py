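"""Synthesize concentration pools matching printed summary targets.

Field-level mycotoxin data are right-skewed and LOQ-censored, so the model
family is a point mass at the censoring floor plus a lognormal body censored
at the floor.  The three free parameters (censored fraction, log-mean,
log-sd) are calibrated by derivative-free search against the target median,
mean and fraction-above-limit, using common random numbers so the objective
is deterministic and the result reproducible under seed.  The single largest
value is then set to the target maximum exactly.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.optimize import minimize
from scipy.special import expit

from .chain_sim import ConcentrationPool
from .model import HazardFrameworkError

__all__ = [
    "PoolSummaryTargets",
    "InfeasibleTargetsError",
    "CalibrationError",
    "DEFAULT_TOLERANCES",
    "synthesize_pool",
    "validate_pool",
    "StatCheck",
    "PoolValidationReport",
]


class InfeasibleTargetsError(HazardFrameworkError, ValueError):
    """Target summaries that no pool can satisfy."""


class CalibrationError(HazardFrameworkError, RuntimeError):
    """Calibration failed to reach the requested tolerances."""


class PoolSummaryTargets(BaseModel):
    """Printed summary statistics a synthetic pool must reproduce."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    median: float
    mean: float
    max: float
    frac_above_limit: float
    limit: float
    floor: float
    size: int = 293

    @model_validator(mode="after")
    def _check(self) -> "PoolSummaryTargets":
        if self.size < 3:
            raise ValueError("pool size must be >= 3")
        if not 0.0 <= self.frac_above_limit <= 1.0:
            raise ValueError("frac_above_limit must lie in [0, 1]")
        if self.floor < 0 or self.limit <= 0:
            raise ValueError("floor must be >= 0 and limit > 0")
        return self


def check_feasibility(targets: PoolSummaryTargets) -> None:
    """Raise :class:`InfeasibleTargetsError` on order-constraint violations."""
    t = targets
    if not t.floor <= t.median <= t.max:
        raise InfeasibleTargetsError(
            f"need floor <= median <= max, got ({t.floor}, {t.median}, {t.max})")
    if t.mean > t.max or t.mean < t.floor:
        raise InfeasibleTargetsError(f"mean {t.mean} outside [floor, max]")
    if t.frac_above_limit > 0 and t.max <= t.limit:
        raise InfeasibleTargetsError(
            f"frac_above_limit {t.frac_above_limit} > 0 requires max > limit "
            f"({t.max} <= {t.limit})")
    if t.frac_above_limit == 0 and t.max > t.limit:
        raise InfeasibleTargetsError(
            f"max {t.max} exceeds limit {t.limit} but frac_above_limit is 0")


DEFAULT_TOLERANCES: dict[str, float] = {
    "median_rel": 0.05,   # |median - target| / target
    "mean_rel": 0.05,     # |mean - target| / target
    "frac_abs": 0.005,    # |frac_above - target|, absolute (0.5 percentage points)
    "max_exact": 0.0,     # realised max == target max
    "min_floor": 0.0,     # realised min >= floor
}


def _realize(x: np.ndarray, z: np.ndarray, u: np.ndarray,
             t: PoolSummaryTargets) -> np.ndarray:
    """Pool for parameters x = (logit p_floor, mu, log sigma) on fixed (z, u)."""
    p = expit(x[0])
    mu, sigma = x[1], math.exp(x[2])
    body = np.exp(mu + sigma * z)
    vals = np.where(u < p, t.floor, np.maximum(body, t.floor))
    vals[int(np.argmax(vals))] = t.max
    return vals


def _objective(x: np.ndarray, z: np.ndarray, u: np.ndarray,
               t: PoolSummaryTargets) -> float:
    vals = _realize(x, z, u, t)
    med = float(np.median(vals))
    mean = float(vals.mean())
    frac = float(np.mean(vals > t.limit))
    # smooth surrogate of the exceedance count guides the simplex between the
    # steps of the hard count
    with np.errstate(divide="ignore"):
        soft = float(np.mean(expit(np.log(np.maximum(vals, 1e-12) / t.limit) / 0.05)))
    med_ref = t.median if t.median > 0 else 1.0
    err = ((med - t.median) / med_ref / 0.04) ** 2
    err += ((mean - t.mean) / t.mean / 0.04) ** 2
    err += ((frac - t.frac_above_limit) / 0.004) ** 2
    err += 0.1 * ((soft - t.frac_above_limit) / 0.004) ** 2
    # replacement of the argmax must leave no other value above the target max
    err += 100.0 * int(np.sum(vals > t.max))
    return err


def _candidate_starts(t: PoolSummaryTargets, rng: np.random.Generator,
                      n: int = 256) -> np.ndarray:
    """Coarse random starts over a wide parameter box informed by the targets."""
    body_median = t.median if t.median > t.floor else max(t.floor, 1e-6)
    mu_lo = math.log(max(body_median, 1e-6)) - 2.5
    mu_hi = math.log(max(t.mean, body_median)) + 1.5
    starts = np.column_stack([
        rng.uniform(-3.0, 3.0, n),       # logit censored fraction
        rng.uniform(mu_lo, mu_hi, n),    # log-mean of the body
        rng.uniform(-1.2, 1.2, n),       # log of the log-sd
    ])
    ratio = max(t.mean / max(t.median, 1e-6), 1.05)
    sigma0 = math.sqrt(2.0 * math.log(ratio))
    p0 = 0.4 if t.median <= t.floor else 0.05
    starts[0] = [math.log(p0 / (1 - p0)), math.log(body_median), math.log(sigma0)]
    return starts


def _calibrate_once(targets: PoolSummaryTargets, rng: np.random.Generator,
                    n_starts: int = 256, n_polish: int = 4) -> np.ndarray:
    """One calibration attempt on a fresh common-random-numbers draw.

    The objective is piecewise constant in the exceedance count, so a single
    simplex start is basin-sensitive; instead the best few of many coarse
    random starts are polished.
    """
    z = rng.standard_normal(targets.size)
    u = rng.random(targets.size)
    starts = _candidate_starts(targets, rng, n_starts)
    scores = np.array([_objective(x, z, u, targets) for x in starts])
    best_x, best_f = None, math.inf
    for idx in np.argsort(scores)[:n_polish]:
        res = minimize(_objective, starts[idx], args=(z, u, targets),
                       method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-12})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if best_f < 1e-9:
            break
    return _realize(best_x, z, u, targets)


def synthesize_pool(targets: PoolSummaryTargets, seed: int,
                    tolerances: Optional[dict[str, float]] = None,
                    max_restarts: int = 8, analyte: str = "",
                    limit_kind: str = "maximum_limit") -> ConcentrationPool:
    """Generate a pool of ``targets.size`` values matching the targets.

    Deterministic under ``seed``; raises :class:`InfeasibleTargetsError` for
    contradictory targets and :class:`CalibrationError` if no restart reaches
    the tolerances.
    """
    check_feasibility(targets)
    tol = DEFAULT_TOLERANCES if tolerances is None else tolerances
    for child in np.random.SeedSequence(seed).spawn(max_restarts):
        rng = np.random.default_rng(child)
        vals = _calibrate_once(targets, rng)
        pool = ConcentrationPool(values=tuple(float(v) for v in vals),
                                 analyte=analyte or "analyte", limit=targets.limit,
                                 limit_kind=limit_kind)  # type: ignore[arg-type]
        report = validate_pool(pool, targets, tol)
        if report.passed:
            return pool
    raise CalibrationError(
        f"could not calibrate pool to targets within tolerances after "
        f"{max_restarts} restarts")


class StatCheck(BaseModel):
    """One statistic of a validation report."""

    model_config = ConfigDict(frozen=True)

    statistic: str
    target: float
    realised: float
    tolerance: float
    passed: bool


class PoolValidationReport(BaseModel):
    """Machine-readable per-statistic pass/fail report."""

    model_config = ConfigDict(frozen=True)

    checks: tuple[StatCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)


def validate_pool(pool: ConcentrationPool, targets: PoolSummaryTargets,
                  tolerances: Optional[dict[str, float]] = None) -> PoolValidationReport:
    """Check a pool's realised summaries against the targets.

    ``tolerances`` selects which checks run (empty mapping = vacuous pass);
    unknown keys are rejected.
    """
    tol = DEFAULT_TOLERANCES if tolerances is None else tolerances
    unknown = set(tol) - set(DEFAULT_TOLERANCES)
    if unknown:
        raise HazardFrameworkError(f"unknown tolerance keys: {sorted(unknown)}")
    vals = np.asarray(pool.values, dtype=float)
    med, mean = float(np.median(vals)), float(vals.mean())
    frac = float(np.mean(vals > targets.limit))
    checks: list[StatCheck] = []
    if "median_rel" in tol:
        ref = targets.median if targets.median > 0 else 1.0
        err = abs(med - targets.median) / ref
        checks.append(StatCheck(statistic="median", target=targets.median, realised=med,
                                tolerance=tol["median_rel"], passed=err <= tol["median_rel"]))
    if "mean_rel" in tol:
        err = abs(mean - targets.mean) / targets.mean
        checks.append(StatCheck(statistic="mean", target=targets.mean, realised=mean,
                                tolerance=tol["mean_rel"], passed=err <= tol["mean_rel"]))
    if "frac_abs" in tol:
        err = abs(frac - targets.frac_above_limit)
        checks.append(StatCheck(statistic="frac_above_limit", target=targets.frac_above_limit,
                                realised=frac, tolerance=tol["frac_abs"],
                                passed=err <= tol["frac_abs"]))
    if "max_exact" in tol:
        realised_max = float(vals.max())
        checks.append(StatCheck(statistic="max", target=targets.max, realised=realised_max,
                                tolerance=tol["max_exact"],
                                passed=abs(realised_max - targets.max) <= tol["max_exact"]))
    if "min_floor" in tol:
        realised_min = float(vals.min())
        checks.append(StatCheck(statistic="min", target=targets.floor, realised=realised_min,
                                tolerance=tol["min_floor"],
                                passed=realised_min >= targets.floor - tol["min_floor"]))
    return PoolValidationReport(checks=tuple(checks))
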