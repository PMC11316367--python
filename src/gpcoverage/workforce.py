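"""Physician-level workforce arithmetic.

Full-time-equivalent (FTE) weighting against the 40 h/week standard working
period, unit-level list accounting, age-weighted patient units used for
risk-adjusted list sizes, and the extra FTE implied by a shifting case-mix.

Portuguese primary care counts a GP's workload in *weighted units*: each
patient counts 1.0, except children aged 0–6 (1.5), adults 65–74 (2.0) and
adults 75+ (2.5). The regulatory reference list size is 1 917 weighted
units per GP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import BandMappingError, ConsistencyError, UndefinedRatioError

#: Standard full-time working week, hours.
STANDARD_WEEKLY_HOURS = 40.0

#: Regulatory reference list size, in weighted units per GP.
REFERENCE_LIST_WEIGHTED_UNITS = 1917

#: National December-2023 workforce: headcount and FTE as published.
GP_HEADCOUNT_2023 = 6934
GP_FTE_2023 = 5395
#: FTE share of headcount as printed in the source report ...
PRINTED_FTE_SHARE_2023 = 0.839
#: ... and as recomputed from the two published counts (5395/6934).
COMPUTED_FTE_SHARE_2023 = GP_FTE_2023 / GP_HEADCOUNT_2023


@dataclass(frozen=True)
class PhysicianRecord:
    """One physician: contracted weekly hours and assigned list size."""

    physician_id: str
    unit_id: str
    weekly_hours: float
    list_size: int

    def __post_init__(self) -> None:
        if self.weekly_hours < 0:
            raise ValueError(f"physician {self.physician_id!r}: negative weekly_hours")
        if self.list_size < 0:
            raise ValueError(f"physician {self.physician_id!r}: negative list_size")


def fte_from_hours(
    weekly_hours: float,
    standard_hours: float = STANDARD_WEEKLY_HOURS,
    cap: float | None = None,
) -> float:
    """Full-time equivalent of a weekly-hours figure.

    FTE = weekly_hours / standard_hours. Values above 1 are permitted by
    default (overtime); pass ``cap=1.0`` to truncate.
    """
    if weekly_hours < 0:
        raise ValueError(f"weekly_hours must be >= 0, got {weekly_hours}")
    if standard_hours <= 0:
        raise ValueError(f"standard_hours must be > 0, got {standard_hours}")
    fte = weekly_hours / standard_hours
    if cap is not None:
        fte = min(fte, cap)
    return fte


def unit_fte(
    roster: Iterable[PhysicianRecord],
    standard_hours: float = STANDARD_WEEKLY_HOURS,
    cap: float | None = None,
) -> float:
    """Total FTE of a unit's physician roster (0 for an empty roster)."""
    return sum(fte_from_hours(p.weekly_hours, standard_hours, cap) for p in roster)


def unassigned_from_lists(
    enrolled: int,
    roster: Iterable[PhysicianRecord],
    literal_fte_weighting: bool = False,
    standard_hours: float = STANDARD_WEEKLY_HOURS,
) -> float:
    """Patients without an assigned GP implied by the unit's lists.

    Default: enrolled − Σ list_size — every patient on some list is
    assigned, regardless of their GP's contracted hours. With
    ``literal_fte_weighting=True`` each list is instead multiplied by its
    physician's FTE weight before summing (enrolled − Σ FTE_i·L_i), which
    undercounts assignment wherever part-timers hold lists; it is provided
    for sensitivity comparison only.
    """
    roster = list(roster)
    if literal_fte_weighting:
        covered = sum(
            fte_from_hours(p.weekly_hours, standard_hours) * p.list_size for p in roster
        )
    else:
        covered = sum(p.list_size for p in roster)
    if covered > enrolled:
        raise ConsistencyError(
            f"assigned patients ({covered}) exceed enrolled ({enrolled})"
        )
    return enrolled - covered


def list_ratio(enrolled: int, unassigned: int, gp_fte: float) -> float:
    """Patient-to-GP ratio: patients *with* an assigned GP per FTE GP."""
    if not 0 <= unassigned <= enrolled:
        raise ValueError(
            f"need 0 <= unassigned <= enrolled, got ({unassigned}, {enrolled})"
        )
    if gp_fte == 0:
        raise UndefinedRatioError("list ratio undefined for a unit with gp_fte = 0")
    return (enrolled - unassigned) / gp_fte


# -- age-weighted patient units --------------------------------------------


@dataclass(frozen=True)
class AgeBand:
    """Closed integer-age band [min_age, max_age]; max_age None means open."""

    min_age: int
    max_age: int | None
    weight: float

    @property
    def label(self) -> str:
        return f"{self.min_age}_{self.max_age}" if self.max_age is not None else f"{self.min_age}p"

    def contains(self, age: int) -> bool:
        return age >= self.min_age and (self.max_age is None or age <= self.max_age)


@dataclass(frozen=True)
class AgeWeights:
    """Ordered, non-overlapping age bands covering 0–∞ with positive weights."""

    bands: tuple[AgeBand, ...] = field(
        default_factory=lambda: (
            AgeBand(0, 6, 1.5),
            AgeBand(7, 64, 1.0),
            AgeBand(65, 74, 2.0),
            AgeBand(75, None, 2.5),
        )
    )

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("AgeWeights needs at least one band")
        bands = sorted(self.bands, key=lambda b: b.min_age)
        if bands[0].min_age != 0:
            raise ValueError("age bands must start at age 0")
        for prev, cur in zip(bands, bands[1:]):
            if prev.max_age is None or cur.min_age != prev.max_age + 1:
                raise ValueError("age bands must partition the age axis without gaps")
        if bands[-1].max_age is not None:
            raise ValueError("last age band must be open-ended")
        if any(b.weight <= 0 for b in self.bands):
            raise ValueError("age-band weights must be positive")
        object.__setattr__(self, "bands", tuple(bands))

    def weight_for_age(self, age: int) -> float:
        for band in self.bands:
            if band.contains(age):
                return band.weight
        raise BandMappingError(f"age {age} not covered by any band")

    def weight_for_label(self, label: str) -> float:
        norm = label.removeprefix("age_").replace("-", "_").replace("+", "p")
        for band in self.bands:
            if band.label == norm:
                return band.weight
        raise BandMappingError(
            f"age band {label!r} does not match any configured band "
            f"({[b.label for b in self.bands]})"
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "AgeWeights":
        """Load bands from YAML/JSON: a list of {min_age, max_age, weight}."""
        spec = yaml.safe_load(Path(path).read_text())
        return cls(
            bands=tuple(
                AgeBand(int(b["min_age"]),
                        None if b.get("max_age") is None else int(b["max_age"]),
                        float(b["weight"]))
                for b in spec
            )
        )


DEFAULT_AGE_WEIGHTS = AgeWeights()


def weighted_units(
    age_band_counts: Mapping[str, int],
    weights: AgeWeights = DEFAULT_AGE_WEIGHTS,
) -> tuple[float, float]:
    """Total weighted patient units and weighted units per patient.

    Returns ``(total, per_patient)`` with total = Σ weight_b × count_b.
    Raises :class:`BandMappingError` for an unresolvable band label and
    :class:`UndefinedRatioError` when there are zero patients.
    """
    if any(c < 0 for c in age_band_counts.values()):
        raise ValueError("age-band counts must be non-negative")
    total = sum(weights.weight_for_label(band) * count
                for band, count in age_band_counts.items())
    patients = sum(age_band_counts.values())
    if patients == 0:
        raise UndefinedRatioError("weighted units per patient undefined for 0 patients")
    return total, total / patients


def required_additional_gps(
    gp_fte: float, wu_per_patient_0: float, wu_per_patient_1: float
) -> float:
    """Extra FTE needed to hold weighted workload per FTE constant.

    When the average weighted units per patient move from w0 to w1 while
    total patients stay fixed, the workforce must scale by w1/w0:
    additional FTE = gp_fte × (w1/w0 − 1). Negative when the case-mix
    lightens; exactly zero iff w0 == w1.
    """
    if wu_per_patient_0 <= 0:
        raise ValueError(f"wu_per_patient_0 must be > 0, got {wu_per_patient_0}")
    if gp_fte <= 0 or wu_per_patient_1 <= 0:
        raise ValueError("gp_fte and wu_per_patient_1 must be > 0")
    return gp_fte * (wu_per_patient_1 / wu_per_patient_0 - 1.0)


def read_roster(path: str | Path) -> list[PhysicianRecord]:
    """Read a physician roster CSV: physician_id,unit_id,weekly_hours,list_size."""
    import pandas as pd

    from .errors import SchemaError

    df = pd.read_csv(path, dtype={"physician_id": str, "unit_id": str})
    for col in ("physician_id", "unit_id", "weekly_hours", "list_size"):
        if col not in df.columns:
            raise SchemaError(f"roster missing required column {col!r}")
    return [
        PhysicianRecord(r.physician_id, r.unit_id, float(r.weekly_hours), int(r.list_size))
        for r in df.itertuples()
    ]


def write_roster(roster: Iterable[PhysicianRecord], path: str | Path) -> Path:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "physician_id": p.physician_id,
                "unit_id": p.unit_id,
                "weekly_hours": p.weekly_hours,
                "list_size": p.list_size,
            }
            for p in roster
        ],
        columns=["physician_id", "unit_id", "weekly_hours", "list_size"],
    )
    df.to_csv(path, index=False)
    return Path(path)
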