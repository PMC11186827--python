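"""Turn quantitative evidence into ordinal LOW/MEDIUM/HIGH scores.

All classifiers are pure functions of (value, rule set).  Boundary values
fall in MEDIUM where a middle class exists ("<30 / 30-100 / >100" style
wording), except where a classifier is explicitly binary (exceedance, HBGV).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .model import (
    ClassificationRuleSet,
    DomainError,
    HazardLevel,
    OccurrenceEvidence,
    PersistenceEvidence,
    SeverityEvidence,
    TransferEvidence,
)

__all__ = [
    "classify_dt50",
    "combine_compartment_persistence",
    "classify_microbial_persistence",
    "classify_transfer_log_koc",
    "classify_accumulation_baf",
    "classify_occurrence_concentration",
    "classify_occurrence_exceedance",
    "normalize_hbgv_to_daily",
    "classify_severity_chemical",
    "classify_severity_antibiotic",
    "classify_severity_microbial",
    "occurrence_level",
    "persistence_level",
    "transfer_level",
    "severity_level",
]


def classify_dt50(dt50_days: float, rules: Optional[ClassificationRuleSet] = None) -> HazardLevel:
    """Persistence class of a half-life: LOW < 30 d <= MEDIUM <= 100 d < HIGH."""
    rules = rules or ClassificationRuleSet()
    if dt50_days <= 0:
        raise DomainError(f"DT50 must be > 0 days, got {dt50_days}")
    b = rules.dt50_bounds
    if dt50_days < b.low_upper:
        return HazardLevel.LOW
    if dt50_days > b.high_lower:
        return HazardLevel.HIGH
    return HazardLevel.MEDIUM


def combine_compartment_persistence(levels: Sequence[HazardLevel]) -> HazardLevel:
    """Collapse per-compartment persistence levels conservatively (maximum)."""
    if not levels:
        raise DomainError("need at least one compartment persistence level")
    return max(HazardLevel.parse(l) for l in levels)


def classify_microbial_persistence(
    log_reduction_days: float,
    waiting_time_days: float,
    rules: Optional[ClassificationRuleSet] = None,
) -> HazardLevel:
    """Classify microbial persistence from achieved log reduction.

    ``waiting_time_days / log_reduction_days`` logs are achieved before
    harvest; >= 4 logs scores LOW, < 2 logs HIGH, MEDIUM in between.
    """
    rules = rules or ClassificationRuleSet()
    if log_reduction_days <= 0:
        raise DomainError(f"days per log reduction must be > 0, got {log_reduction_days}")
    if waiting_time_days < 0:
        raise DomainError(f"waiting time must be >= 0 days, got {waiting_time_days}")
    logs = waiting_time_days / log_reduction_days
    b = rules.log_reduction_bounds
    if logs >= b.low_lower:
        return HazardLevel.LOW
    if logs < b.high_upper:
        return HazardLevel.HIGH
    return HazardLevel.MEDIUM


def classify_transfer_log_koc(log_koc: float, rules: Optional[ClassificationRuleSet] = None) -> HazardLevel:
    """Plant-uptake likelihood from mobility: HIGH < 1.0 <= MEDIUM < 2.0 <= LOW (log10 K_OC)."""
    rules = rules or ClassificationRuleSet()
    b = rules.koc_bounds
    if log_koc < b.high_upper:
        return HazardLevel.HIGH
    if log_koc >= b.low_lower:
        return HazardLevel.LOW
    return HazardLevel.MEDIUM


def classify_accumulation_baf(baf: float, rules: Optional[ClassificationRuleSet] = None) -> HazardLevel:
    """Accumulation class of a bio-accumulation factor: LOW <= 1 < MEDIUM <= 5 < HIGH."""
    rules = rules or ClassificationRuleSet()
    if baf < 0:
        raise DomainError(f"BAF must be >= 0, got {baf}")
    b = rules.baf_bounds
    if baf <= b.low_upper:
        return HazardLevel.LOW
    if baf > b.high_lower:
        return HazardLevel.HIGH
    return HazardLevel.MEDIUM


def classify_occurrence_concentration(
    evidence: Iterable[OccurrenceEvidence],
    hazard_class: str,
    rules: Optional[ClassificationRuleSet] = None,
) -> HazardLevel:
    """Worst-case occurrence class across matrices.

    Takes the maximum concentration over all numeric evidence items and
    applies the chemical or microbial bounds (HIGH is inclusive at the
    high bound).
    """
    rules = rules or ClassificationRuleSet()
    items = [ev for ev in evidence if ev.kind.endswith("_concentration")]
    if not items:
        raise DomainError("no concentration evidence to classify")
    kinds = {ev.kind for ev in items}
    if len(kinds) > 1:
        raise DomainError(f"mixed concentration units/kinds: {sorted(kinds)}")
    expected = f"{hazard_class}_concentration"
    if kinds != {expected}:
        raise DomainError(f"concentration kind {kinds.pop()!r} does not match "
                          f"hazard_class {hazard_class!r}")
    worst = max(ev.value for ev in items)
    b = rules.chem_conc_bounds if hazard_class == "chemical" else rules.micro_conc_bounds
    if worst < b.low_upper:
        return HazardLevel.LOW
    if worst >= b.high_lower:
        return HazardLevel.HIGH
    return HazardLevel.MEDIUM


def classify_occurrence_exceedance(frac_exceeding: float,
                                   rules: Optional[ClassificationRuleSet] = None) -> HazardLevel:
    """Binary occurrence rule: HIGH iff the exceedance fraction is > 3%."""
    rules = rules or ClassificationRuleSet()
    if not 0.0 <= frac_exceeding <= 1.0:
        raise DomainError(f"exceedance fraction must lie in [0, 1], got {frac_exceeding}")
    return HazardLevel.HIGH if frac_exceeding > rules.exceedance_threshold else HazardLevel.LOW


def normalize_hbgv_to_daily(value: float, basis: str) -> float:
    """Bring a health-based guidance value onto the per-day scale (weekly / 7)."""
    if value < 0:
        raise DomainError(f"HBGV must be >= 0, got {value}")
    if basis == "per_day":
        return value
    if basis == "per_week":
        return value / 7.0
    raise DomainError(f"unknown HBGV basis {basis!r}")


def classify_severity_chemical(evidence: SeverityEvidence,
                               rules: Optional[ClassificationRuleSet] = None) -> HazardLevel:
    """Chemical severity: HIGH on any toxicity endpoint flag, or on a daily
    guidance value (ADI/TDI/BMDL10, weekly values divided by 7) <= 10 ug/kg bw/day."""
    rules = rules or ClassificationRuleSet()
    if evidence.endpoint_flags:
        return HazardLevel.HIGH
    if evidence.hbgv_value is None:
        raise DomainError("no usable severity evidence (need HBGV or endpoint flags)")
    daily = normalize_hbgv_to_daily(evidence.hbgv_value, evidence.hbgv_basis)
    return HazardLevel.HIGH if daily <= rules.hbgv_daily_cutoff else HazardLevel.LOW


def classify_severity_antibiotic(chronic: HazardLevel, resistance: HazardLevel) -> HazardLevel:
    """Combine binary chronic-toxicity and resistance classes.

    Both HIGH -> HIGH; exactly one HIGH -> MEDIUM; both LOW -> LOW.  MEDIUM
    inputs are rejected (the rule is defined on binary components only).
    """
    chronic = HazardLevel.parse(chronic)
    resistance = HazardLevel.parse(resistance)
    for name, lvl in (("chronic", chronic), ("resistance", resistance)):
        if lvl is HazardLevel.MEDIUM:
            raise DomainError(f"antibiotic severity {name} component must be LOW or HIGH")
    n_high = (chronic is HazardLevel.HIGH) + (resistance is HazardLevel.HIGH)
    return (HazardLevel.LOW, HazardLevel.MEDIUM, HazardLevel.HIGH)[n_high]


def classify_severity_microbial(daly_per_case: float,
                                rules: Optional[ClassificationRuleSet] = None) -> HazardLevel:
    """Pathogen severity from disease burden: LOW < 0.01 <= MEDIUM <= 0.1 < HIGH DALY/case."""
    rules = rules or ClassificationRuleSet()
    if daly_per_case < 0:
        raise DomainError(f"DALY/case must be >= 0, got {daly_per_case}")
    b = rules.daly_bounds
    if daly_per_case > b.high_lower:
        return HazardLevel.HIGH
    if daly_per_case >= b.low_upper:
        return HazardLevel.MEDIUM
    return HazardLevel.LOW


# ---------------------------------------------------------------------------
# Evidence dispatchers (level + provenance string)
# ---------------------------------------------------------------------------

def occurrence_level(evidence: Sequence[OccurrenceEvidence], hazard_class: str,
                     rules: ClassificationRuleSet) -> tuple[HazardLevel, str]:
    """Collapse a hazard's occurrence evidence to one level (worst case)."""
    if not evidence:
        raise DomainError("no occurrence evidence")
    levels: list[tuple[HazardLevel, str]] = []
    conc = [ev for ev in evidence if ev.kind.endswith("_concentration")]
    if conc:
        lvl = classify_occurrence_concentration(conc, hazard_class, rules)
        worst = max(ev.value for ev in conc)
        levels.append((lvl, f"max concentration {worst:g} over {len(conc)} matrix(es)"))
    for ev in evidence:
        if ev.kind == "exceedance_fraction":
            levels.append((classify_occurrence_exceedance(ev.value, rules),
                           f"exceedance fraction {ev.value:g} vs threshold "
                           f"{rules.exceedance_threshold:g}"))
        elif ev.kind == "assigned_level":
            levels.append((ev.level, f"assigned level {ev.level.code}"
                           + (f" in {ev.matrix}" if ev.matrix else "")))
    best = max(levels, key=lambda t: t[0])
    return best[0], best[1]


def persistence_level(evidence: PersistenceEvidence,
                      rules: ClassificationRuleSet) -> tuple[HazardLevel, str]:
    """Collapse persistence evidence; an assigned level overrides numeric data."""
    if evidence.assigned_level is not None:
        return evidence.assigned_level, f"assigned level {evidence.assigned_level.code}"
    if evidence.dt50_days_by_compartment:
        per = {c: classify_dt50(v, rules) for c, v in evidence.dt50_days_by_compartment.items()}
        lvl = combine_compartment_persistence(list(per.values()))
        detail = "; ".join(f"{c}: DT50 {evidence.dt50_days_by_compartment[c]:g} d -> {l.code}"
                           for c, l in per.items())
        return lvl, f"max over compartments ({detail})"
    if evidence.log_reduction_days is not None:
        wait = evidence.waiting_time_days or 0.0
        lvl = classify_microbial_persistence(evidence.log_reduction_days, wait, rules)
        return lvl, (f"{wait:g} d waiting / {evidence.log_reduction_days:g} d per log = "
                     f"{wait / evidence.log_reduction_days:.2f} logs")
    raise DomainError("persistence evidence is empty")


def transfer_level(evidence: TransferEvidence,
                   rules: ClassificationRuleSet) -> tuple[HazardLevel, str]:
    """Classify transfer (log K_OC) or accumulation (BAF) evidence."""
    if evidence.kind == "assigned_level":
        return evidence.level, f"assigned level {evidence.level.code}"
    if evidence.kind == "log_koc":
        return (classify_transfer_log_koc(evidence.value, rules),
                f"log K_OC {evidence.value:g}")
    return (classify_accumulation_baf(evidence.value, rules),
            f"BAF {evidence.value:g}")


def severity_level(evidence: SeverityEvidence,
                   rules: ClassificationRuleSet) -> tuple[HazardLevel, str]:
    """Classify severity evidence according to its kind."""
    if evidence.kind == "microbial":
        return (classify_severity_microbial(evidence.daly_per_case, rules),
                f"{evidence.daly_per_case:g} DALY/case")
    if evidence.kind == "antibiotic":
        chronic = classify_severity_chemical(evidence, rules)
        resistance = (HazardLevel.HIGH if evidence.antibiotic_choice_class >= 2
                      else HazardLevel.LOW)
        lvl = classify_severity_antibiotic(chronic, resistance)
        return lvl, (f"chronic {chronic.code} (HBGV {evidence.hbgv_value:g} "
                     f"{evidence.hbgv_basis}) x resistance {resistance.code} "
                     f"(choice class {evidence.antibiotic_choice_class})")
    lvl = classify_severity_chemical(evidence, rules)
    if evidence.endpoint_flags:
        return lvl, f"endpoint flags {sorted(evidence.endpoint_flags)}"
    return lvl, f"HBGV {evidence.hbgv_value:g} ug/kg bw {evidence.hbgv_basis}"
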