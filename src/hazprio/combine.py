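"""Combination matrices: presence (environment or accumulation route),
priority (presence x severity), end-to-end prioritisation and the one-level
sensitivity read-off.

The matrices are data, not code: the defaults below can be swapped for a
variant via a YAML config (see :func:`load_matrix_config`), e.g. to
down-weight transfer.  Totality and monotonicity are asserted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict

from . import classify
from .model import (
    ClassificationRuleSet,
    CombinationMatrix,
    ConfigError,
    HazardFrameworkError,
    HazardLevel,
    HazardProfile,
    PriorityRecord,
)

__all__ = [
    "ENVIRONMENT_PRESENCE_RULES",
    "ACCUMULATION_PRESENCE_RULES",
    "PRIORITY_RULES",
    "MatrixSet",
    "DEFAULT_MATRICES",
    "load_matrix_config",
    "presence_environment",
    "presence_accumulation",
    "prioritize",
    "prioritize_hazard",
    "sensitivity_one_level",
    "SensitivityEntry",
]

# (occurrence, persistence, transfer) -> presence in final product
ENVIRONMENT_PRESENCE_RULES = [
    "L,L,* -> L",
    "L,M,L -> L",
    "L,M,M/H -> M",
    "L,H,* -> M",
    "M,L/M,* -> M",
    "M,H,* -> H",
    "H,L,* -> M",
    "H,M,L -> M",
    "H,M,M/H -> H",
    "H,H,* -> H",
]

# (occurrence, accumulation) -> presence in final product
ACCUMULATION_PRESENCE_RULES = [
    "L,L -> L",
    "L,M/H -> M",
    "M,L/M -> M",
    "M,H -> H",
    "H,L/M -> M",
    "H,H -> H",
]

# (presence, health effect) -> prioritisation
PRIORITY_RULES = [
    "L,L/M -> L",
    "L,H -> M",
    "M,L -> L",
    "M,M -> M",
    "M,H -> H",
    "H,L -> M",
    "H,M/H -> H",
]


@dataclass(frozen=True)
class MatrixSet:
    """The three combination matrices used for prioritisation."""

    environment: CombinationMatrix
    accumulation: CombinationMatrix
    priority: CombinationMatrix


def _default_matrices() -> MatrixSet:
    return MatrixSet(
        environment=CombinationMatrix.from_rules(3, ENVIRONMENT_PRESENCE_RULES,
                                                 name="presence_environment"),
        accumulation=CombinationMatrix.from_rules(2, ACCUMULATION_PRESENCE_RULES,
                                                  name="presence_accumulation"),
        priority=CombinationMatrix.from_rules(2, PRIORITY_RULES, name="priority"),
    )


DEFAULT_MATRICES = _default_matrices()


def load_matrix_config(source: "str | Path | dict") -> MatrixSet:
    """Load a matrix set from YAML: keys ``presence_environment``,
    ``presence_accumulation`` and ``priority``, each a list of rule strings
    like ``"H,M,L/M -> H"``.  Missing keys fall back to the defaults."""
    if isinstance(source, dict):
        data = source
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"matrix config not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("matrix config must be a mapping of rule lists")
    known = {"presence_environment", "presence_accumulation", "priority"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown matrix config keys: {sorted(unknown)}")
    env = data.get("presence_environment")
    acc = data.get("presence_accumulation")
    pri = data.get("priority")
    return MatrixSet(
        environment=(CombinationMatrix.from_rules(3, env, name="presence_environment")
                     if env else DEFAULT_MATRICES.environment),
        accumulation=(CombinationMatrix.from_rules(2, acc, name="presence_accumulation")
                      if acc else DEFAULT_MATRICES.accumulation),
        priority=(CombinationMatrix.from_rules(2, pri, name="priority")
                  if pri else DEFAULT_MATRICES.priority),
    )


def presence_environment(occurrence: HazardLevel, persistence: HazardLevel,
                         transfer: HazardLevel,
                         matrices: Optional[MatrixSet] = None) -> HazardLevel:
    """Presence in the final product via the environment route."""
    m = (matrices or DEFAULT_MATRICES).environment
    return m(occurrence, persistence, transfer)


def presence_accumulation(occurrence: HazardLevel, accumulation: HazardLevel,
                          matrices: Optional[MatrixSet] = None) -> HazardLevel:
    """Presence in the final product via the accumulation route."""
    m = (matrices or DEFAULT_MATRICES).accumulation
    return m(occurrence, accumulation)


def prioritize(presence: HazardLevel, health: HazardLevel,
               matrices: Optional[MatrixSet] = None) -> HazardLevel:
    """Final risk score from presence and health-effect levels."""
    m = (matrices or DEFAULT_MATRICES).priority
    return m(presence, health)


def _presence_from_levels(route: str, levels: dict[str, HazardLevel],
                          matrices: MatrixSet) -> HazardLevel:
    if route == "environment":
        return matrices.environment(levels["occurrence"], levels["persistence"],
                                    levels["transfer"])
    return matrices.accumulation(levels["occurrence"], levels["accumulation"])


def prioritize_hazard(profile: HazardProfile,
                      rules: Optional[ClassificationRuleSet] = None,
                      matrices: Optional[MatrixSet] = None) -> PriorityRecord:
    """Run all classifiers for a profile and combine them into a priority.

    Returns a :class:`PriorityRecord` with one level per indicator, the
    presence and priority levels, and a provenance note per level.
    """
    rules = rules or ClassificationRuleSet()
    matrices = matrices or DEFAULT_MATRICES
    try:
        levels: dict[str, HazardLevel] = {}
        provenance: dict[str, str] = {}
        levels["occurrence"], provenance["occurrence"] = classify.occurrence_level(
            profile.occurrence, profile.hazard_class, rules)
        if profile.route == "environment":
            levels["persistence"], provenance["persistence"] = classify.persistence_level(
                profile.persistence, rules)
            levels["transfer"], provenance["transfer"] = classify.transfer_level(
                profile.transfer, rules)
        else:
            levels["accumulation"], provenance["accumulation"] = classify.transfer_level(
                profile.transfer, rules)
        severity, provenance["severity"] = classify.severity_level(profile.severity, rules)
        presence = _presence_from_levels(profile.route, levels, matrices)
        provenance["presence"] = f"{profile.route} matrix over {[l.code for l in levels.values()]}"
        priority = matrices.priority(presence, severity)
        provenance["priority"] = f"priority matrix ({presence.code}, {severity.code})"
    except HazardFrameworkError as exc:
        raise type(exc)(f"{profile.hazard_id}: {exc}") from exc
    return PriorityRecord(hazard_id=profile.hazard_id, route=profile.route,
                          levels=levels, presence=presence, severity=severity,
                          priority=priority, provenance=provenance)


class SensitivityEntry(BaseModel):
    """One row of the one-level sensitivity read-off."""

    model_config = ConfigDict(frozen=True)

    indicator: str
    direction: int           # -1 or +1
    base_level: HazardLevel
    perturbed_level: HazardLevel
    presence: HazardLevel
    priority: HazardLevel
    priority_changed: bool


def sensitivity_one_level(profile: HazardProfile,
                          rules: Optional[ClassificationRuleSet] = None,
                          matrices: Optional[MatrixSet] = None) -> list[SensitivityEntry]:
    """Perturb each underlying indicator, the severity and the presence score
    by one level (clamped at LOW/HIGH) and report the resulting priority.

    Clamped no-op perturbations are omitted.
    """
    rules = rules or ClassificationRuleSet()
    matrices = matrices or DEFAULT_MATRICES
    record = prioritize_hazard(profile, rules, matrices)
    out: list[SensitivityEntry] = []

    def add(indicator: str, base: HazardLevel, presence: HazardLevel,
            severity: HazardLevel, direction: int, perturbed: HazardLevel) -> None:
        priority = matrices.priority(presence, severity)
        out.append(SensitivityEntry(
            indicator=indicator, direction=direction, base_level=base,
            perturbed_level=perturbed, presence=presence, priority=priority,
            priority_changed=priority is not record.priority))

    for indicator, base in record.levels.items():
        for direction in (-1, +1):
            perturbed = base.shifted(direction)
            if perturbed is base:
                continue
            shifted = dict(record.levels, **{indicator: perturbed})
            presence = _presence_from_levels(profile.route, shifted, matrices)
            add(indicator, base, presence, record.severity, direction, perturbed)
    for direction in (-1, +1):
        perturbed = record.severity.shifted(direction)
        if perturbed is not record.severity:
            add("severity", record.severity, record.presence, perturbed,
                direction, perturbed)
    for direction in (-1, +1):
        perturbed = record.presence.shifted(direction)
        if perturbed is not record.presence:
            add("presence", record.presence, perturbed, record.severity,
                direction, perturbed)
    return out
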