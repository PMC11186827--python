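"""Domain types, hazard registry I/O and classification rule-set configuration.

The ordinal scale, the evidence bundles attached to a hazard, and every
numeric threshold used downstream live here.  All thresholds carry defaults
reproducing the shipped case studies but are fully configurable through a
flat YAML file (see :func:`load_ruleset`).
"""

from __future__ import annotations

import csv
import enum
import io
import itertools
from pathlib import Path
from typing import Iterable, Literal, Optional, TextIO

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "HazardLevel",
    "OccurrenceEvidence",
    "PersistenceEvidence",
    "TransferEvidence",
    "SeverityEvidence",
    "HazardProfile",
    "Bounds",
    "InverseBounds",
    "ClassificationRuleSet",
    "CombinationMatrix",
    "PriorityRecord",
    "HazardFrameworkError",
    "DomainError",
    "ConfigError",
    "RegistryError",
    "load_ruleset",
    "save_ruleset",
    "load_hazard_registry",
    "write_hazard_registry",
    "REGISTRY_COLUMNS",
]


class HazardFrameworkError(Exception):
    """Base class for all package errors."""


class DomainError(HazardFrameworkError, ValueError):
    """An input outside a classifier's domain (negative DT50, fraction > 1, ...)."""


class ConfigError(HazardFrameworkError, ValueError):
    """Malformed rule-set or matrix configuration."""


class RegistryError(HazardFrameworkError, ValueError):
    """Malformed hazard registry table."""


# ---------------------------------------------------------------------------
# Ordinal scale
# ---------------------------------------------------------------------------

class HazardLevel(enum.IntEnum):
    """Three-level ordinal score: LOW < MEDIUM < HIGH.

    Serialised as single letters "L"/"M"/"H"; parsing is case-insensitive and
    accepts full words and the numeric scores 1/2/3.
    """

    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def code(self) -> str:
        return {1: "L", 2: "M", 3: "H"}[int(self)]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code

    @classmethod
    def parse(cls, text: "str | int | HazardLevel") -> "HazardLevel":
        if isinstance(text, HazardLevel):
            return text
        if isinstance(text, int):
            return cls(text)
        key = str(text).strip().lower()
        table = {
            "l": cls.LOW, "low": cls.LOW, "1": cls.LOW,
            "m": cls.MEDIUM, "medium": cls.MEDIUM, "2": cls.MEDIUM,
            "h": cls.HIGH, "high": cls.HIGH, "3": cls.HIGH,
        }
        try:
            return table[key]
        except KeyError:
            raise DomainError(f"not a hazard level: {text!r}") from None

    def shifted(self, delta: int) -> "HazardLevel":
        """Return the level moved by ``delta`` steps, clamped at LOW/HIGH."""
        return HazardLevel(min(max(int(self) + delta, 1), 3))


LEVELS = (HazardLevel.LOW, HazardLevel.MEDIUM, HazardLevel.HIGH)


# ---------------------------------------------------------------------------
# Evidence bundles
# ---------------------------------------------------------------------------

OccurrenceKind = Literal[
    "chemical_concentration", "microbial_concentration",
    "exceedance_fraction", "assigned_level",
]


class OccurrenceEvidence(BaseModel):
    """One occurrence observation in one matrix (substrate)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: OccurrenceKind
    value: Optional[float] = None
    level: Optional[HazardLevel] = None
    matrix: str = ""

    @model_validator(mode="after")
    def _check(self) -> "OccurrenceEvidence":
        if self.kind == "assigned_level":
            if self.level is None or self.value is not None:
                raise ValueError("assigned_level occurrence needs a level and no value")
        else:
            if self.value is None or self.level is not None:
                raise ValueError(f"{self.kind} occurrence needs a numeric value only")
            if self.value < 0:
                raise ValueError("occurrence value must be non-negative")
            if self.kind == "exceedance_fraction" and not 0.0 <= self.value <= 1.0:
                raise ValueError("exceedance fraction must lie in [0, 1]")
        return self


class PersistenceEvidence(BaseModel):
    """Persistence of a hazard in its environment.

    Chemicals carry DT50 values per compartment; microbes a days-per-log
    reduction rate plus a waiting time; either kind may instead carry a
    directly assigned level (which takes precedence).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    dt50_days_by_compartment: dict[str, float] = Field(default_factory=dict)
    assigned_level: Optional[HazardLevel] = None
    log_reduction_days: Optional[float] = None
    waiting_time_days: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "PersistenceEvidence":
        for comp, v in self.dt50_days_by_compartment.items():
            if v <= 0:
                raise ValueError(f"DT50 for {comp!r} must be > 0")
        if self.log_reduction_days is not None and self.log_reduction_days <= 0:
            raise ValueError("log_reduction_days must be > 0")
        if self.waiting_time_days is not None and self.waiting_time_days < 0:
            raise ValueError("waiting_time_days must be >= 0")
        has_microbial = self.log_reduction_days is not None
        if not (self.dt50_days_by_compartment or self.assigned_level or has_microbial):
            raise ValueError("persistence evidence is empty")
        return self


TransferKind = Literal["log_koc", "bioaccumulation_factor", "assigned_level"]


class TransferEvidence(BaseModel):
    """Transfer to edible parts (log K_OC) or accumulation (BAF) evidence."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: TransferKind
    value: Optional[float] = None
    level: Optional[HazardLevel] = None

    @model_validator(mode="after")
    def _check(self) -> "TransferEvidence":
        if self.kind == "assigned_level":
            if self.level is None or self.value is not None:
                raise ValueError("assigned_level transfer needs a level and no value")
        else:
            if self.value is None or self.level is not None:
                raise ValueError(f"{self.kind} transfer needs a numeric value only")
            if self.kind == "bioaccumulation_factor" and self.value < 0:
                raise ValueError("BAF must be >= 0")
        return self


SeverityKind = Literal["chemical", "microbial", "antibiotic"]
EndpointFlag = Literal["carcinogenic", "mutagenic", "reprotoxic", "repeated_dose"]
HbgvBasis = Literal["per_day", "per_week"]


class SeverityEvidence(BaseModel):
    """Human-health severity evidence.

    Chemicals: a health-based guidance value (ADI/TDI/BMDL10, daily or weekly
    basis) and/or toxicity endpoint flags.  Antibiotics additionally carry the
    choice class (second/third-choice antibiotics score high on resistance).
    Microbes: the disease burden in DALY per case.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: SeverityKind
    hbgv_value: Optional[float] = None
    hbgv_basis: HbgvBasis = "per_day"
    endpoint_flags: frozenset[EndpointFlag] = frozenset()
    antibiotic_choice_class: Optional[int] = None
    daly_per_case: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "SeverityEvidence":
        if self.hbgv_value is not None and self.hbgv_value < 0:
            raise ValueError("hbgv_value must be >= 0")
        if self.daly_per_case is not None and self.daly_per_case < 0:
            raise ValueError("daly_per_case must be >= 0")
        if self.kind == "microbial":
            if self.daly_per_case is None:
                raise ValueError("microbial severity requires daly_per_case")
        else:
            if self.hbgv_value is None and not self.endpoint_flags:
                raise ValueError(f"{self.kind} severity requires hbgv_value or endpoint_flags")
        if self.kind == "antibiotic":
            if self.antibiotic_choice_class not in (1, 2, 3):
                raise ValueError("antibiotic severity requires choice class in {1,2,3}")
        elif self.antibiotic_choice_class is not None:
            raise ValueError("antibiotic_choice_class only valid for kind='antibiotic'")
        return self


class HazardProfile(BaseModel):
    """One hazard's full evidence bundle plus its combination route."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    hazard_id: str
    hazard_class: Literal["chemical", "microbial"]
    route: Literal["environment", "accumulation"]
    occurrence: tuple[OccurrenceEvidence, ...]
    persistence: Optional[PersistenceEvidence] = None
    transfer: Optional[TransferEvidence] = None
    severity: SeverityEvidence

    @model_validator(mode="after")
    def _check(self) -> "HazardProfile":
        if not self.occurrence:
            raise ValueError("at least one occurrence evidence item is required")
        if self.route == "environment":
            if self.persistence is None:
                raise ValueError("environment route requires persistence evidence")
            if self.transfer is None:
                raise ValueError("environment route requires transfer evidence")
            if self.transfer.kind == "bioaccumulation_factor":
                raise ValueError("environment route transfer must be log_koc or an assigned level")
        else:
            if self.transfer is None or self.transfer.kind == "log_koc":
                raise ValueError("accumulation route requires a BAF or an assigned accumulation level")
            if self.persistence is not None:
                raise ValueError("accumulation route carries no persistence evidence")
        for ev in self.occurrence:
            if ev.kind == "chemical_concentration" and self.hazard_class != "chemical":
                raise ValueError("chemical concentration on a non-chemical hazard")
            if ev.kind == "microbial_concentration" and self.hazard_class != "microbial":
                raise ValueError("microbial concentration on a non-microbial hazard")
        return self


# ---------------------------------------------------------------------------
# Rule set
# ---------------------------------------------------------------------------

def _as_bound_mapping(value, keys: tuple[str, str]):
    if isinstance(value, (list, tuple)):
        if len(value) != 2:
            raise ValueError(f"bound pair needs exactly two values, got {value!r}")
        return dict(zip(keys, value))
    return value


class Bounds(BaseModel):
    """Bound pair on a scale where larger values mean higher risk."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    low_upper: float
    high_lower: float

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, value):
        return _as_bound_mapping(value, ("low_upper", "high_lower"))

    @model_validator(mode="after")
    def _ordered(self) -> "Bounds":
        if self.low_upper > self.high_lower:
            raise ValueError(f"low_upper ({self.low_upper}) must be <= high_lower ({self.high_lower})")
        return self


class InverseBounds(BaseModel):
    """Bound pair on a scale where larger values mean *lower* risk (log K_OC, achieved logs)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    high_upper: float
    low_lower: float

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, value):
        return _as_bound_mapping(value, ("high_upper", "low_lower"))

    @model_validator(mode="after")
    def _ordered(self) -> "InverseBounds":
        if self.high_upper > self.low_lower:
            raise ValueError(f"high_upper ({self.high_upper}) must be <= low_lower ({self.low_lower})")
        return self


class ClassificationRuleSet(BaseModel):
    """Every numeric threshold turning evidence into levels.

    Defaults reproduce the shipped case studies:

    * DT50 (days): LOW < 30 <= MEDIUM <= 100 < HIGH
    * achieved log-reduction (microbes): LOW >= 4 logs, HIGH < 2 logs
    * log10 K_OC: HIGH < 1.0 <= MEDIUM < 2.0 <= LOW
    * BAF: LOW <= 1 < MEDIUM <= 5 < HIGH
    * chemical occurrence (ng/g dm): LOW < 1e4 <= MEDIUM < 2e4 <= HIGH
    * microbial occurrence (cfu/g dm): LOW < 1e6 <= MEDIUM < 1e7 <= HIGH
    * exceedance: HIGH iff fraction > 0.03 (binary)
    * HBGV: HIGH iff <= 10 ug/kg bw/day
    * DALY/case: LOW < 0.01 <= MEDIUM <= 0.1 < HIGH
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    dt50_bounds: Bounds = Field(default_factory=lambda: Bounds(low_upper=30.0, high_lower=100.0))
    log_reduction_bounds: InverseBounds = Field(
        default_factory=lambda: InverseBounds(high_upper=2.0, low_lower=4.0))
    koc_bounds: InverseBounds = Field(
        default_factory=lambda: InverseBounds(high_upper=1.0, low_lower=2.0))
    baf_bounds: Bounds = Field(default_factory=lambda: Bounds(low_upper=1.0, high_lower=5.0))
    chem_conc_bounds: Bounds = Field(default_factory=lambda: Bounds(low_upper=1e4, high_lower=2e4))
    micro_conc_bounds: Bounds = Field(default_factory=lambda: Bounds(low_upper=1e6, high_lower=1e7))
    exceedance_threshold: float = 0.03
    hbgv_daily_cutoff: float = 10.0
    daly_bounds: Bounds = Field(default_factory=lambda: Bounds(low_upper=0.01, high_lower=0.1))

    @model_validator(mode="after")
    def _check(self) -> "ClassificationRuleSet":
        if not 0.0 <= self.exceedance_threshold <= 1.0:
            raise ValueError("exceedance_threshold must lie in [0, 1]")
        if self.hbgv_daily_cutoff < 0:
            raise ValueError("hbgv_daily_cutoff must be >= 0")
        return self


def load_ruleset(source: "None | str | Path | dict | TextIO" = None) -> ClassificationRuleSet:
    """Load a rule set from YAML (path, text, stream or mapping).

    Missing keys fall back to defaults; unknown keys are rejected.  ``None``
    or an empty document yields the default rule set.
    """
    if source is None:
        return ClassificationRuleSet()
    if isinstance(source, dict):
        data = source
    else:
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).suffix in {".yml", ".yaml"}):
            text = Path(source).read_text()
        elif hasattr(source, "read"):
            text = source.read()
        else:
            text = source
        data = yaml.safe_load(text)
    if data is None:
        return ClassificationRuleSet()
    if not isinstance(data, dict):
        raise ConfigError(f"rule-set config must be a mapping, got {type(data).__name__}")
    try:
        return ClassificationRuleSet(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid rule-set config: {exc}") from exc


def save_ruleset(rules: ClassificationRuleSet, path: "str | Path") -> None:
    Path(path).write_text(yaml.safe_dump(rules.model_dump(), sort_keys=False))


# ---------------------------------------------------------------------------
# Combination matrices
# ---------------------------------------------------------------------------

_TOKEN = {"L": (HazardLevel.LOW,), "M": (HazardLevel.MEDIUM,), "H": (HazardLevel.HIGH,),
          "*": LEVELS}


def _expand_token(token: str) -> tuple[HazardLevel, ...]:
    token = token.strip().upper()
    if token == "*":
        return LEVELS
    parts = token.split("/")
    out = []
    for p in parts:
        if p not in ("L", "M", "H"):
            raise ConfigError(f"bad level token {token!r} in matrix rule")
        out.append(HazardLevel.parse(p))
    return tuple(out)


class CombinationMatrix:
    """Total, monotone mapping from level tuples to a level.

    Built from rule strings like ``"H,M,L/M -> H"`` where ``*`` matches any
    level and ``A/B`` alternates.  Totality, uniqueness and monotonicity in
    every argument are asserted on construction.
    """

    def __init__(self, arity: int, entries: dict[tuple[HazardLevel, ...], HazardLevel],
                 name: str = ""):
        if arity not in (2, 3):
            raise ConfigError("matrix arity must be 2 or 3")
        self.arity = arity
        self.name = name
        self.entries = dict(entries)
        self._check_total()
        self._check_monotone()

    @classmethod
    def from_rules(cls, arity: int, rules: Iterable[str], name: str = "") -> "CombinationMatrix":
        entries: dict[tuple[HazardLevel, ...], HazardLevel] = {}
        for rule in rules:
            try:
                lhs, rhs = rule.split("->")
            except ValueError:
                raise ConfigError(f"matrix rule {rule!r} must contain '->'") from None
            tokens = [t for t in lhs.split(",")]
            if len(tokens) != arity:
                raise ConfigError(f"matrix rule {rule!r} has {len(tokens)} inputs, expected {arity}")
            out = HazardLevel.parse(rhs.strip())
            for combo in itertools.product(*(_expand_token(t) for t in tokens)):
                if combo in entries:
                    raise ConfigError(f"matrix {name!r}: duplicate assignment for {combo}")
                entries[combo] = out
        return cls(arity, entries, name=name)

    def _check_total(self) -> None:
        missing = [c for c in itertools.product(LEVELS, repeat=self.arity)
                   if c not in self.entries]
        if missing:
            raise ConfigError(f"matrix {self.name!r} is not total; missing {missing[:3]}...")
        if len(self.entries) != 3 ** self.arity:
            extra = set(self.entries) - set(itertools.product(LEVELS, repeat=self.arity))
            raise ConfigError(f"matrix {self.name!r} has invalid keys {extra}")

    def _check_monotone(self) -> None:
        for combo, out in self.entries.items():
            for i in range(self.arity):
                if combo[i] is HazardLevel.HIGH:
                    continue
                bumped = list(combo)
                bumped[i] = HazardLevel(int(combo[i]) + 1)
                if self.entries[tuple(bumped)] < out:
                    raise ConfigError(
                        f"matrix {self.name!r} not monotone at {combo} (argument {i})")

    def __call__(self, *levels: HazardLevel) -> HazardLevel:
        if len(levels) != self.arity:
            raise DomainError(f"matrix {self.name!r} takes {self.arity} levels")
        return self.entries[tuple(HazardLevel.parse(l) for l in levels)]

    def to_rules(self) -> list[str]:
        return [",".join(l.code for l in combo) + " -> " + out.code
                for combo, out in sorted(self.entries.items())]


# ---------------------------------------------------------------------------
# Priority record
# ---------------------------------------------------------------------------

class PriorityRecord(BaseModel):
    """End-to-end prioritisation result for one hazard, with provenance."""

    model_config = ConfigDict(extra="forbid")

    hazard_id: str
    route: Literal["environment", "accumulation"]
    levels: dict[str, HazardLevel]
    presence: HazardLevel
    severity: HazardLevel
    priority: HazardLevel
    provenance: dict[str, str] = Field(default_factory=dict)


# ---------------------------------------------------------------------------
# Hazard registry CSV
# ---------------------------------------------------------------------------

REGISTRY_COLUMNS = ["hazard_id", "hazard_class", "route", "evidence_kind",
                    "compartment", "value", "units", "basis"]

_CONC_UNITS = {"chemical": "ng/g dm", "microbial": "cfu/g dm"}

_EVIDENCE_KINDS = {
    "occurrence_concentration", "occurrence_exceedance", "occurrence_level",
    "persistence_dt50", "persistence_log_reduction", "persistence_waiting_time",
    "persistence_level",
    "transfer_log_koc", "transfer_level",
    "accumulation_baf", "accumulation_level",
    "severity_hbgv", "severity_daly", "severity_endpoints",
    "severity_antibiotic_choice",
}


def _float(row: dict, what: str) -> float:
    try:
        return float(row["value"])
    except (TypeError, ValueError):
        raise RegistryError(f"{row['hazard_id']}: {what} needs a numeric value, "
                            f"got {row['value']!r}") from None


def _build_profile(hazard_id: str, rows: list[dict]) -> HazardProfile:
    classes = {r["hazard_class"] for r in rows}
    routes = {r["route"] for r in rows}
    if len(classes) != 1 or len(routes) != 1:
        raise RegistryError(f"{hazard_id}: inconsistent hazard_class/route across rows")
    hazard_class, route = classes.pop(), routes.pop()
    if hazard_class not in ("chemical", "microbial"):
        raise RegistryError(f"{hazard_id}: unknown hazard_class {hazard_class!r}")
    if route not in ("environment", "accumulation"):
        raise RegistryError(f"{hazard_id}: unknown route {route!r}")

    occurrence: list[OccurrenceEvidence] = []
    dt50: dict[str, float] = {}
    pers_level = log_red = wait = None
    transfer: Optional[TransferEvidence] = None
    sev: dict = {}

    for row in rows:
        kind = row["evidence_kind"]
        if kind not in _EVIDENCE_KINDS:
            raise RegistryError(f"{hazard_id}: unknown evidence_kind {kind!r}")
        units = (row.get("units") or "").strip()
        comp = (row.get("compartment") or "").strip()
        if kind == "occurrence_concentration":
            expected = _CONC_UNITS[hazard_class]
            if units != expected:
                raise RegistryError(f"{hazard_id}: occurrence units {units!r} do not match "
                                    f"hazard_class {hazard_class!r} (expected {expected!r})")
            occurrence.append(OccurrenceEvidence(
                kind=f"{hazard_class}_concentration",  # type: ignore[arg-type]
                value=_float(row, kind), matrix=comp))
        elif kind == "occurrence_exceedance":
            occurrence.append(OccurrenceEvidence(
                kind="exceedance_fraction", value=_float(row, kind), matrix=comp))
        elif kind == "occurrence_level":
            occurrence.append(OccurrenceEvidence(
                kind="assigned_level", level=HazardLevel.parse(row["value"]), matrix=comp))
        elif kind == "persistence_dt50":
            if units != "days":
                raise RegistryError(f"{hazard_id}: DT50 units must be 'days', got {units!r}")
            if not comp:
                raise RegistryError(f"{hazard_id}: DT50 row needs a compartment label")
            dt50[comp] = _float(row, kind)
        elif kind == "persistence_log_reduction":
            log_red = _float(row, kind)
        elif kind == "persistence_waiting_time":
            wait = _float(row, kind)
        elif kind == "persistence_level":
            pers_level = HazardLevel.parse(row["value"])
        elif kind == "transfer_log_koc":
            transfer = TransferEvidence(kind="log_koc", value=_float(row, kind))
        elif kind == "accumulation_baf":
            transfer = TransferEvidence(kind="bioaccumulation_factor", value=_float(row, kind))
        elif kind in ("transfer_level", "accumulation_level"):
            transfer = TransferEvidence(kind="assigned_level", level=HazardLevel.parse(row["value"]))
        elif kind == "severity_hbgv":
            if units != "ug/kg bw":
                raise RegistryError(f"{hazard_id}: HBGV units must be 'ug/kg bw', got {units!r}")
            basis = (row.get("basis") or "per_day").strip()
            sev["hbgv_value"] = _float(row, kind)
            sev["hbgv_basis"] = basis
        elif kind == "severity_daly":
            if units != "DALY/case":
                raise RegistryError(f"{hazard_id}: DALY units must be 'DALY/case', got {units!r}")
            sev["daly_per_case"] = _float(row, kind)
        elif kind == "severity_endpoints":
            flags = [f.strip() for f in str(row["value"]).split("|") if f.strip()]
            sev["endpoint_flags"] = frozenset(flags)
        elif kind == "severity_antibiotic_choice":
            sev["antibiotic_choice_class"] = int(_float(row, kind))

    if sev.get("antibiotic_choice_class") is not None:
        sev_kind = "antibiotic"
    elif hazard_class == "microbial":
        sev_kind = "microbial"
    else:
        sev_kind = "chemical"

    persistence = None
    if dt50 or pers_level is not None or log_red is not None:
        persistence = PersistenceEvidence(
            dt50_days_by_compartment=dt50, assigned_level=pers_level,
            log_reduction_days=log_red, waiting_time_days=wait)

    try:
        return HazardProfile(
            hazard_id=hazard_id, hazard_class=hazard_class, route=route,
            occurrence=tuple(occurrence), persistence=persistence,
            transfer=transfer, severity=SeverityEvidence(kind=sev_kind, **sev))
    except ValueError as exc:
        raise RegistryError(f"{hazard_id}: {exc}") from exc


def load_hazard_registry(source: "str | Path | TextIO") -> list[HazardProfile]:
    """Read a hazard registry CSV into validated :class:`HazardProfile` objects.

    One profile per ``hazard_id`` row-group; groups keep file order.
    """
    if hasattr(source, "read"):
        stream: TextIO = source  # type: ignore[assignment]
    else:
        stream = io.StringIO(Path(source).read_text())
    reader = csv.DictReader(stream)
    if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != REGISTRY_COLUMNS:
        raise RegistryError(
            f"registry header must be exactly {','.join(REGISTRY_COLUMNS)}, "
            f"got {reader.fieldnames}")
    groups: dict[str, list[dict]] = {}
    for i, row in enumerate(reader, start=2):
        hazard_id = (row.get("hazard_id") or "").strip()
        if not hazard_id:
            raise RegistryError(f"row {i}: empty hazard_id")
        groups.setdefault(hazard_id, []).append(row)
    return [_build_profile(hid, rows) for hid, rows in groups.items()]


def _profile_rows(p: HazardProfile) -> list[list[str]]:
    def row(kind: str, comp: str = "", value: str = "", units: str = "", basis: str = ""):
        return [p.hazard_id, p.hazard_class, p.route, kind, comp, value, units, basis]

    fmt = lambda v: format(float(v), ".12g")
    rows = []
    for ev in p.occurrence:
        if ev.kind == "assigned_level":
            rows.append(row("occurrence_level", ev.matrix, ev.level.code))
        elif ev.kind == "exceedance_fraction":
            rows.append(row("occurrence_exceedance", ev.matrix, fmt(ev.value), "fraction"))
        else:
            rows.append(row("occurrence_concentration", ev.matrix, fmt(ev.value),
                            _CONC_UNITS[p.hazard_class]))
    if p.persistence is not None:
        pe = p.persistence
        for comp, v in pe.dt50_days_by_compartment.items():
            rows.append(row("persistence_dt50", comp, fmt(v), "days"))
        if pe.log_reduction_days is not None:
            rows.append(row("persistence_log_reduction", "", fmt(pe.log_reduction_days), "days/log10"))
        if pe.waiting_time_days is not None:
            rows.append(row("persistence_waiting_time", "", fmt(pe.waiting_time_days), "days"))
        if pe.assigned_level is not None:
            rows.append(row("persistence_level", "", pe.assigned_level.code))
    if p.transfer is not None:
        te = p.transfer
        if te.kind == "log_koc":
            rows.append(row("transfer_log_koc", "", fmt(te.value), "log10"))
        elif te.kind == "bioaccumulation_factor":
            rows.append(row("accumulation_baf", "", fmt(te.value), "ratio"))
        else:
            kind = "accumulation_level" if p.route == "accumulation" else "transfer_level"
            rows.append(row(kind, "", te.level.code))
    se = p.severity
    if se.hbgv_value is not None:
        rows.append(row("severity_hbgv", "", fmt(se.hbgv_value), "ug/kg bw", se.hbgv_basis))
    if se.endpoint_flags:
        rows.append(row("severity_endpoints", "", "|".join(sorted(se.endpoint_flags))))
    if se.antibiotic_choice_class is not None:
        rows.append(row("severity_antibiotic_choice", "", str(se.antibiotic_choice_class)))
    if se.daly_per_case is not None:
        rows.append(row("severity_daly", "", fmt(se.daly_per_case), "DALY/case"))
    return rows


def write_hazard_registry(profiles: Iterable[HazardProfile], path: "str | Path | TextIO") -> None:
    """Write profiles back to the registry CSV schema (round-trip safe)."""
    own = not hasattr(path, "write")
    stream: TextIO = open(path, "w", newline="") if own else path  # type: ignore[arg-type]
    try:
        w = csv.writer(stream)
        w.writerow(REGISTRY_COLUMNS)
        for p in profiles:
            w.writerows(_profile_rows(p))
    finally:
        if own:
            stream.close()
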