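"""Variable schema: meta-variable declarations driving gridding and imputation.

Each clinical meta-variable carries a kind (ordinal / binary / categorical), a
unit, an imputation mode, a clinically defined normal value and optional
severity-level predicates used by the instability-history features.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

GRID_STEP_MIN = 5
BINS_PER_HOUR = 12
MAX_GRID_DAYS = 28
MAX_GRID_BINS = MAX_GRID_DAYS * 24 * BINS_PER_HOUR  # 8064


class VarKind(str, enum.Enum):
    ORDINAL = "ordinal"
    BINARY = "binary"
    CATEGORICAL = "categorical"


class FillMode(str, enum.Enum):
    INDEFINITE = "indefinite_ffill"
    FIXED = "limited_ffill_fixed"
    ADAPTIVE = "limited_ffill_adaptive"
    EXACT = "exact_grid_point"


#: Airway category codes (categorical meta-variable ``airway``).
AIRWAY_NONE = 0
AIRWAY_INTUBATED = 1
AIRWAY_TRACHEOSTOMY = 2
AIRWAY_MASK = 3
AIRWAY_HELMET = 4
AIRWAY_MOUTHPIECE = 5
AIRWAY_NASAL = 6

#: Ventilator mode codes.
MODE_STANDBY = 1
MODE_CONTROLLED = 2
MODE_SPONTANEOUS = 3
MODE_NIV = 4
MODE_HIGHFLOW = 5
MODE_CPAP = 6


@dataclass(frozen=True)
class SeverityLevel:
    """One severity threshold predicate, e.g. ``op='lt', threshold=90``."""

    op: str  # one of {"lt", "le", "gt", "ge"}
    threshold: float

    def check(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.op == "lt":
            return v < self.threshold
        if self.op == "le":
            return v <= self.threshold
        if self.op == "gt":
            return v > self.threshold
        if self.op == "ge":
            return v >= self.threshold
        raise ValueError(f"unknown severity op {self.op!r}")


@dataclass(frozen=True)
class VariableSpec:
    variable_id: str
    kind: VarKind = VarKind.ORDINAL
    unit: str = ""
    fill_mode: FillMode = FillMode.ADAPTIVE
    fill_horizon_min: Optional[float] = None  # required for FIXED
    normal_value: Optional[float] = None
    severity_levels: tuple[SeverityLevel, ...] = ()
    is_medication: bool = False
    is_important: bool = False

    def __post_init__(self):
        if self.fill_mode is FillMode.FIXED:
            if self.fill_horizon_min is None or self.fill_horizon_min <= 0:
                raise ValueError(
                    f"{self.variable_id}: limited_ffill_fixed needs a positive horizon"
                )
        if len(self.severity_levels) > 3:
            raise ValueError(f"{self.variable_id}: at most 3 severity levels")


class Schema:
    """Ordered collection of :class:`VariableSpec`, keyed by variable id."""

    def __init__(self, specs: list[VariableSpec]):
        self._specs: dict[str, VariableSpec] = {}
        for s in specs:
            if s.variable_id in self._specs:
                raise ValueError(f"duplicate variable id {s.variable_id!r}")
            self._specs[s.variable_id] = s

    def __getitem__(self, variable_id: str) -> VariableSpec:
        return self._specs[variable_id]

    def __contains__(self, variable_id: str) -> bool:
        return variable_id in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def variable_ids(self) -> list[str]:
        return list(self._specs)

    def severity_level_of(self, variable_id: str, values: np.ndarray) -> np.ndarray:
        """Map values to severity level 0 (none) .. n (worst); NaN -> -1."""
        spec = self[variable_id]
        v = np.asarray(values, dtype=float)
        out = np.zeros(v.shape, dtype=np.int64)
        for i, lev in enumerate(spec.severity_levels, start=1):
            out[lev.check(v)] = i
        out[np.isnan(v)] = -1
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for s in self:
            d = dataclasses.asdict(s)
            d["kind"] = s.kind.value
            d["fill_mode"] = s.fill_mode.value
            d["severity_levels"] = [
                {"op": l.op, "threshold": l.threshold} for l in s.severity_levels
            ]
            del d["variable_id"]
            out[s.variable_id] = d
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"variables": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        specs = []
        for vid, entry in d.items():
            specs.append(
                VariableSpec(
                    variable_id=vid,
                    kind=VarKind(entry.get("kind", "ordinal")),
                    unit=entry.get("unit", ""),
                    fill_mode=FillMode(entry.get("fill_mode", "limited_ffill_adaptive")),
                    fill_horizon_min=entry.get("fill_horizon_min"),
                    normal_value=entry.get("normal_value"),
                    severity_levels=tuple(
                        SeverityLevel(l["op"], float(l["threshold"]))
                        for l in entry.get("severity_levels", [])
                    ),
                    is_medication=bool(entry.get("is_medication", False)),
                    is_important=bool(entry.get("is_important", False)),
                )
            )
        return cls(specs)

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d["variables"])


def default_schema() -> Schema:
    """The schema shipped with the synthetic cohort generator.

    Severity thresholds are clinically plausible defaults and fully
    user-overridable via YAML.
    """
    S = SeverityLevel
    specs = [
        VariableSpec("hr", VarKind.ORDINAL, "bpm", FillMode.ADAPTIVE, None, 80.0,
                     (S("gt", 110), S("gt", 130), S("gt", 150)), is_important=True),
        VariableSpec("spo2", VarKind.ORDINAL, "%", FillMode.ADAPTIVE, None, 97.0,
                     (S("lt", 92), S("lt", 88), S("lt", 84)), is_important=True),
        VariableSpec("rr", VarKind.ORDINAL, "1/min", FillMode.ADAPTIVE, None, 15.0,
                     (S("ge", 25), S("ge", 30), S("ge", 35)), is_important=True),
        VariableSpec("map", VarKind.ORDINAL, "mmHg", FillMode.ADAPTIVE, None, 80.0,
                     (S("le", 70), S("le", 60), S("le", 50)), is_important=True),
        VariableSpec("gcs", VarKind.ORDINAL, "points", FillMode.FIXED, 24 * 60, 15.0),
        # arterial blood gas panel
        VariableSpec("pao2", VarKind.ORDINAL, "mmHg", FillMode.FIXED, 8 * 60, 90.0,
                     is_important=True),
        VariableSpec("sao2", VarKind.ORDINAL, "%", FillMode.FIXED, 8 * 60, 97.0),
        VariableSpec("paco2", VarKind.ORDINAL, "mmHg", FillMode.FIXED, 8 * 60, 40.0),
        VariableSpec("ph", VarKind.ORDINAL, "pH", FillMode.FIXED, 8 * 60, 7.4),
        VariableSpec("lactate", VarKind.ORDINAL, "mmol/L", FillMode.FIXED, 12 * 60, 1.0,
                     (S("ge", 2.5), S("ge", 4.0), S("ge", 8.0))),
        # ventilator channels
        VariableSpec("vent_mode", VarKind.CATEGORICAL, "code", FillMode.FIXED, 8 * 60, 0.0),
        VariableSpec("peep", VarKind.ORDINAL, "cmH2O", FillMode.FIXED, 4 * 60, 5.0,
                     is_important=True),
        VariableSpec("pressure_support", VarKind.ORDINAL, "cmH2O", FillMode.FIXED, 4 * 60, 8.0),
        VariableSpec("tidal_volume", VarKind.ORDINAL, "mL", FillMode.FIXED, 4 * 60, 450.0),
        VariableSpec("minute_volume", VarKind.ORDINAL, "L/min", FillMode.FIXED, 4 * 60, 7.0),
        VariableSpec("etco2", VarKind.ORDINAL, "mmHg", FillMode.EXACT, None, 0.0),
        VariableSpec("peak_pressure", VarKind.ORDINAL, "cmH2O", FillMode.FIXED, 4 * 60, 15.0),
        VariableSpec("fio2", VarKind.ORDINAL, "fraction", FillMode.FIXED, 12 * 60, 0.21,
                     is_important=True),
        # supplemental oxygen
        VariableSpec("supp_fio2", VarKind.ORDINAL, "fraction", FillMode.FIXED, 12 * 60, 0.21),
        VariableSpec("hiflo_fio2", VarKind.ORDINAL, "fraction", FillMode.FIXED, 12 * 60, 0.21),
        # airway / devices
        VariableSpec("airway", VarKind.CATEGORICAL, "code", FillMode.FIXED, 24 * 60, 0.0),
        VariableSpec("trach", VarKind.BINARY, "flag", FillMode.FIXED, 24 * 60, 0.0),
        VariableSpec("intub", VarKind.BINARY, "flag", FillMode.FIXED, 24 * 60, 0.0),
        # medications
        VariableSpec("norepinephrine", VarKind.ORDINAL, "ug/kg/h", FillMode.INDEFINITE,
                     None, 0.0, is_medication=True),
        VariableSpec("inotrope", VarKind.ORDINAL, "rate", FillMode.INDEFINITE,
                     None, 0.0, is_medication=True),
    ]
    return Schema(specs)


@dataclass
class StayRecord:
    """One ICU stay: static admission metadata plus raw long-format observations.

    Observation arrays are per-variable ``(times, values)`` pairs with
    non-decreasing ``pandas.Timestamp``-convertible times.
    """

    patient_id: str
    admission_time: pd.Timestamp
    discharge_time: pd.Timestamp
    age: float = 65.0
    sex: str = "M"
    height: float = 170.0
    emergency: bool = False
    surgical: bool = False
    apache_group: str = "other"
    elective: bool = False
    death_time: Optional[pd.Timestamp] = None
    observations: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        self.admission_time = pd.Timestamp(self.admission_time)
        self.discharge_time = pd.Timestamp(self.discharge_time)
        if self.admission_time >= self.discharge_time:
            raise ValueError(f"{self.patient_id}: admission must precede discharge")
        if self.death_time is not None:
            self.death_time = pd.Timestamp(self.death_time)
        for vid, (t, v) in self.observations.items():
            t = pd.DatetimeIndex(t).values
            v = np.asarray(v, dtype=float)
            if len(t) != len(v):
                raise ValueError(f"{self.patient_id}/{vid}: times/values length mismatch")
            if len(t) > 1 and np.any(np.diff(t.astype("int64")) < 0):
                raise ValueError(f"{self.patient_id}/{vid}: timestamps must be non-decreasing")
            self.observations[vid] = (t, v)

    @property
    def pre_2009_era(self) -> bool:
        """Admission before 2009-12-06 (legacy ventilation recording)."""
        return self.admission_time < pd.Timestamp("2009-12-06")

    @property
    def pre_2010(self) -> bool:
        return self.admission_time < pd.Timestamp("2010-01-01")

    def statics(self) -> dict:
        return {
            "age": self.age,
            "sex": self.sex,
            "height": self.height,
            "emergency": float(self.emergency),
            "surgical": float(self.surgical),
            "apache_group": self.apache_group,
            "elective": float(self.elective),
        }
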