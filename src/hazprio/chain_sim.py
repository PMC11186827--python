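"""Monte-Carlo batch-mixing simulation: short-chain (single field) vs
conventional (5-10 mixed fields) scenarios, plus milling processing factors.

Draws are with replacement from the empirical concentration pool; the field
count of a conventional batch is discrete-uniform on [n_min, n_max]
inclusive.  All randomness flows through one numpy Generator per call,
seeded explicitly, so identical (pool, reps, seed) give bit-identical
summaries.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .classify import classify_occurrence_exceedance
from .model import ClassificationRuleSet, DomainError, HazardLevel

__all__ = [
    "ConcentrationPool",
    "ScenarioSummary",
    "ScenarioComparison",
    "simulate_short_chain",
    "simulate_mixed_chain",
    "apply_processing_factor",
    "compare_scenarios",
    "read_pool_csv",
    "write_pool_csv",
    "write_comparison_csv",
]


class ConcentrationPool(BaseModel):
    """Empirical batch/field concentrations for one analyte (ug/kg)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    values: tuple[float, ...]
    analyte: str
    limit: float
    limit_kind: Literal["maximum_limit", "guidance"] = "maximum_limit"

    @model_validator(mode="after")
    def _check(self) -> "ConcentrationPool":
        if not self.values:
            raise ValueError("concentration pool must be non-empty")
        if any(v < 0 for v in self.values):
            raise ValueError("concentrations must be >= 0")
        if self.limit <= 0:
            raise ValueError("limit must be > 0")
        return self


class ScenarioSummary(BaseModel):
    """Summary statistics of one simulated scenario (ug/kg)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    scenario: Literal["short_chain", "conventional"]
    reps: int
    n_fields_range: tuple[int, int]
    min: float
    median: float
    mean: float
    max: float
    frac_exceeding: Optional[float]
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSummary":
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.min <= self.median <= self.max:
            raise ValueError("summary must satisfy min <= median <= max")
        if self.frac_exceeding is not None and not 0.0 <= self.frac_exceeding <= 1.0:
            raise ValueError("frac_exceeding must lie in [0, 1]")
        return self


def _summarize(draws: np.ndarray, pool: ConcentrationPool, scenario: str,
               reps: int, n_range: tuple[int, int], seed: int) -> ScenarioSummary:
    return ScenarioSummary(
        scenario=scenario, reps=reps, n_fields_range=n_range,
        min=float(draws.min()), median=float(np.median(draws)),
        mean=float(draws.mean()), max=float(draws.max()),
        frac_exceeding=float(np.mean(draws > pool.limit)), seed=seed)


def simulate_short_chain(pool: ConcentrationPool, reps: int = 100_000, *,
                         seed: int) -> ScenarioSummary:
    """Each rep is one field: a single draw with replacement from the pool."""
    if reps < 1:
        raise DomainError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    values = np.asarray(pool.values, dtype=float)
    draws = rng.choice(values, size=reps, replace=True)
    return _summarize(draws, pool, "short_chain", reps, (1, 1), seed)


def simulate_mixed_chain(pool: ConcentrationPool, n_min: int = 5, n_max: int = 10,
                         reps: int = 100_000, *, seed: int) -> ScenarioSummary:
    """Each rep mixes n ~ DiscreteUniform[n_min, n_max] fields and averages them.

    With ``n_min == n_max`` the field-count draw is skipped, so the RNG stream
    matches :func:`simulate_short_chain`; the degenerate n=1 case is then
    bit-identical to the short chain.
    """
    if reps < 1:
        raise DomainError(f"reps must be >= 1, got {reps}")
    if not 1 <= n_min <= n_max:
        raise DomainError(f"need 1 <= n_min <= n_max, got ({n_min}, {n_max})")
    rng = np.random.default_rng(seed)
    values = np.asarray(pool.values, dtype=float)
    if n_min == n_max:
        ns = np.full(reps, n_min, dtype=np.int64)
    else:
        ns = rng.integers(n_min, n_max + 1, size=reps)
    draws = rng.choice(values, size=int(ns.sum()), replace=True)
    starts = np.concatenate(([0], np.cumsum(ns)[:-1]))
    batches = np.add.reduceat(draws, starts) / ns
    return _summarize(batches, pool, "conventional", reps, (n_min, n_max), seed)


def apply_processing_factor(obj: "ConcentrationPool | ScenarioSummary",
                            factor: float) -> "ConcentrationPool | ScenarioSummary":
    """Scale concentrations (kernels -> flour) by a factor in (0, 1]; limits unchanged.

    On a summary, the location statistics are scaled and ``frac_exceeding`` is
    dropped (it cannot be recovered from a summary); re-simulate on a scaled
    pool to obtain it.
    """
    if not 0.0 < factor <= 1.0:
        raise DomainError(f"processing factor must lie in (0, 1], got {factor}")
    if isinstance(obj, ConcentrationPool):
        return obj.model_copy(update={"values": tuple(v * factor for v in obj.values)})
    if isinstance(obj, ScenarioSummary):
        return obj.model_copy(update={
            "min": obj.min * factor, "median": obj.median * factor,
            "mean": obj.mean * factor, "max": obj.max * factor,
            "frac_exceeding": None if factor != 1.0 else obj.frac_exceeding})
    raise DomainError(f"cannot apply processing factor to {type(obj).__name__}")


class ScenarioComparison(BaseModel):
    """Paired short-chain / conventional summaries plus occurrence levels."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    analyte: str
    limit: float
    short_chain: ScenarioSummary
    conventional: ScenarioSummary
    short_chain_occurrence: HazardLevel
    conventional_occurrence: HazardLevel


def compare_scenarios(pool: ConcentrationPool, reps: int = 100_000,
                      n_min: int = 5, n_max: int = 10, *, seed: int,
                      rules: Optional[ClassificationRuleSet] = None) -> ScenarioComparison:
    """Run both scenarios on the same pool and classify their exceedance rates."""
    rules = rules or ClassificationRuleSet()
    ss = np.random.SeedSequence(seed)
    seed_short, seed_conv = (int(child.generate_state(1)[0]) for child in ss.spawn(2))
    short = simulate_short_chain(pool, reps, seed=seed_short)
    conv = simulate_mixed_chain(pool, n_min, n_max, reps, seed=seed_conv)
    return ScenarioComparison(
        analyte=pool.analyte, limit=pool.limit,
        short_chain=short, conventional=conv,
        short_chain_occurrence=classify_occurrence_exceedance(short.frac_exceeding, rules),
        conventional_occurrence=classify_occurrence_exceedance(conv.frac_exceeding, rules),
    )


# ---------------------------------------------------------------------------
# Pool CSV I/O
# ---------------------------------------------------------------------------

def write_pool_csv(pool: ConcentrationPool, path: "str | Path") -> None:
    """Single-column CSV with ``# key: value`` metadata comment lines."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# analyte: {pool.analyte}\n")
        fh.write("# units: ug/kg\n")
        fh.write(f"# limit: {pool.limit:g}\n")
        fh.write(f"# limit_kind: {pool.limit_kind}\n")
        fh.write("concentration\n")
        for v in pool.values:
            fh.write(format(v, ".12g") + "\n")


def read_pool_csv(path: "str | Path") -> ConcentrationPool:
    meta: dict[str, str] = {}
    values: list[float] = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition(":")
            meta[key.strip()] = val.strip()
        elif not header_seen:
            if line != "concentration":
                raise DomainError(f"pool CSV column header must be 'concentration', got {line!r}")
            header_seen = True
        else:
            values.append(float(line))
    if "analyte" not in meta or "limit" not in meta:
        raise DomainError("pool CSV must declare '# analyte:' and '# limit:' metadata")
    return ConcentrationPool(
        values=tuple(values), analyte=meta["analyte"], limit=float(meta["limit"]),
        limit_kind=meta.get("limit_kind", "maximum_limit"))  # type: ignore[arg-type]


def write_comparison_csv(comparisons: "list[ScenarioComparison]",
                         path: "str | Path | object") -> None:
    """Scenario report: one row per (analyte, scenario); percentages on 0-100."""
    own = not hasattr(path, "write")
    fh = open(path, "w", newline="") if own else path  # type: ignore[arg-type]
    try:
        w = csv.writer(fh)
        w.writerow(["analyte", "scenario", "min", "median", "mean", "max",
                    "pct_exceeding", "occurrence_level", "reps", "n_min", "n_max", "seed"])
        for c in comparisons:
            for s, lvl in ((c.short_chain, c.short_chain_occurrence),
                           (c.conventional, c.conventional_occurrence)):
                w.writerow([c.analyte, s.scenario,
                            f"{s.min:.6g}", f"{s.median:.6g}", f"{s.mean:.6g}",
                            f"{s.max:.6g}", f"{100 * s.frac_exceeding:.6g}", lvl.code,
                            s.reps, s.n_fields_range[0], s.n_fields_range[1], s.seed])
    finally:
        if own:
            fh.close()
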