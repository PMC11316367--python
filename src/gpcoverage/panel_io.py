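"""Read, validate, aggregate and write unit-by-year coverage panels.

The unit of observation is a grouping of primary-care practices (in the
Portuguese system, an ACES) observed once per calendar year with three core
administrative quantities:

* ``enrolled`` (n) — patients enrolled in the unit's practices,
* ``unassigned`` (m) — enrolled patients without an assigned GP,
* ``gp_fte`` (GP) — general-practitioner workforce in full-time equivalents.

Counts are integers; FTE is real. The implied patient-to-GP ratio
``L = (n - m) / GP`` is never stored — it is always recomputed, so the
accounting identity ``m = n - GP * L`` holds exactly on every record.

CSV is the canonical interchange format (UTF-8, comma separated, dot
decimal, one header row, column names equal to the field names below).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CrosswalkError,
    DuplicateRecordError,
    PanelValidationError,
    SchemaError,
)

REQUIRED_COLUMNS = ("unit_id", "region_id", "year", "enrolled", "unassigned", "gp_fte")
COVARIATE_COLUMNS = ("elderly_share", "diabetes_prevalence", "population_density")

#: CSV column name -> canonical age-band label used by workforce.AgeWeights.
AGE_BAND_COLUMNS: Mapping[str, str] = {
    "age_0_6": "0_6",
    "age_7_64": "7_64",
    "age_65_74": "65_74",
    "age_75p": "75p",
}

LEVELS = ("unit", "region", "national")
NATIONAL_ID = "NATIONAL"


@dataclass(frozen=True)
class UnitYearRecord:
    """One unit-year observation of the coverage panel.

    Invariants (enforced by :meth:`validate`):

    * ``0 <= unassigned <= enrolled``
    * ``gp_fte >= 0``; if ``gp_fte == 0`` then ``unassigned == enrolled``
      (with no physicians nobody can hold a list)
    * ``age_band_counts``, when present, sum exactly to ``enrolled``
    """

    unit_id: str
    region_id: str
    year: int
    enrolled: int
    unassigned: int
    gp_fte: float
    elderly_share: float | None = None
    diabetes_prevalence: float | None = None
    population_density: float | None = None
    age_band_counts: Mapping[str, int] | None = None

    @property
    def assigned(self) -> int:
        return self.enrolled - self.unassigned

    @property
    def list_ratio(self) -> float:
        """Patients with a GP per FTE GP; raises if gp_fte == 0."""
        from .workforce import list_ratio

        return list_ratio(self.enrolled, self.unassigned, self.gp_fte)

    def validate(self) -> None:
        key = f"(unit_id={self.unit_id!r}, year={self.year})"
        if self.enrolled < 0 or self.unassigned < 0:
            raise PanelValidationError(f"{key}: negative patient count")
        if self.unassigned > self.enrolled:
            raise PanelValidationError(
                f"{key}: unassigned ({self.unassigned}) exceeds enrolled ({self.enrolled})"
            )
        if self.gp_fte < 0:
            raise PanelValidationError(f"{key}: gp_fte is negative ({self.gp_fte})")
        if self.gp_fte == 0 and self.unassigned != self.enrolled:
            raise PanelValidationError(
                f"{key}: gp_fte = 0 but unassigned ({self.unassigned}) != "
                f"enrolled ({self.enrolled}); with no physicians every patient "
                "is unassigned"
            )
        for name in COVARIATE_COLUMNS[:2]:
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise PanelValidationError(f"{key}: {name} = {value} outside [0, 1]")
        if self.population_density is not None and self.population_density < 0:
            raise PanelValidationError(f"{key}: negative population_density")
        if self.age_band_counts is not None:
            if any(c < 0 for c in self.age_band_counts.values()):
                raise PanelValidationError(f"{key}: negative age-band count")
            total = sum(self.age_band_counts.values())
            if total != self.enrolled:
                raise PanelValidationError(
                    f"{key}: age-band counts sum to {total}, not enrolled "
                    f"({self.enrolled})"
                )


@dataclass
class Panel:
    """A keyed collection of :class:`UnitYearRecord` at one aggregation level."""

    records: dict[tuple[str, int], UnitYearRecord] = field(default_factory=dict)
    level: str = "unit"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise PanelValidationError(f"unknown panel level {self.level!r}")

    @classmethod
    def from_records(
        cls, records: Iterable[UnitYearRecord], level: str = "unit", provenance: str = ""
    ) -> "Panel":
        out: dict[tuple[str, int], UnitYearRecord] = {}
        for rec in records:
            rec.validate()
            key = (rec.unit_id, rec.year)
            if key in out:
                raise DuplicateRecordError(
                    f"duplicate record for unit_id={rec.unit_id!r}, year={rec.year}"
                )
            out[key] = rec
        return cls(records=out, level=level, provenance=provenance)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[UnitYearRecord]:
        return iter(self.records.values())

    def units(self) -> list[str]:
        return sorted({u for u, _ in self.records})

    def years(self) -> list[int]:
        return sorted({y for _, y in self.records})

    def get(self, unit_id: str, year: int) -> UnitYearRecord | None:
        return self.records.get((unit_id, year))

    def series(self, unit_id: str) -> list[UnitYearRecord]:
        """All records for one unit, ordered by year."""
        return sorted(
            (r for (u, _), r in self.records.items() if u == unit_id),
            key=lambda r: r.year,
        )

    def validate(self) -> None:
        for rec in self:
            rec.validate()

    # -- DataFrame bridge ---------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        has_cov = {c: False for c in COVARIATE_COLUMNS}
        has_ages = False
        for rec in self:
            row: dict[str, object] = {
                "unit_id": rec.unit_id,
                "region_id": rec.region_id,
                "year": rec.year,
                "enrolled": rec.enrolled,
                "unassigned": rec.unassigned,
                "gp_fte": rec.gp_fte,
            }
            for c in COVARIATE_COLUMNS:
                v = getattr(rec, c)
                row[c] = v
                if v is not None:
                    has_cov[c] = True
            if rec.age_band_counts is not None:
                has_ages = True
                for col, label in AGE_BAND_COLUMNS.items():
                    row[col] = rec.age_band_counts.get(label, 0)
            rows.append(row)
        columns = list(REQUIRED_COLUMNS)
        columns += [c for c in COVARIATE_COLUMNS if has_cov[c]]
        if has_ages:
            columns += list(AGE_BAND_COLUMNS)
        df = pd.DataFrame(rows, columns=columns)
        df = df.sort_values(["unit_id", "year"], kind="mergesort").reset_index(drop=True)
        for col in ("enrolled", "unassigned"):
            df[col] = df[col].astype("int64")
        for col in AGE_BAND_COLUMNS:
            if col in df.columns:
                df[col] = df[col].astype("Int64")
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, level: str = "unit", provenance: str = ""
    ) -> "Panel":
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            key = f"(unit_id={d['unit_id']!r}, year={d['year']})"
            counts = {}
            for col in ("enrolled", "unassigned"):
                v = d[col]
                if pd.isna(v):
                    raise PanelValidationError(f"{key}: missing {col}")
                if float(v) != int(v):
                    raise PanelValidationError(f"{key}: {col} = {v} is not an integer")
                counts[col] = int(v)
            ages = None
            if any(c in d for c in AGE_BAND_COLUMNS):
                vals = {
                    AGE_BAND_COLUMNS[c]: d[c] for c in AGE_BAND_COLUMNS if c in d
                }
                if all(pd.notna(v) for v in vals.values()):
                    ages = {k: int(v) for k, v in vals.items()}
            covs = {}
            for c in COVARIATE_COLUMNS:
                v = d.get(c)
                covs[c] = None if v is None or pd.isna(v) else float(v)
            records.append(
                UnitYearRecord(
                    unit_id=str(d["unit_id"]),
                    region_id=str(d["region_id"]),
                    year=int(d["year"]),
                    enrolled=counts["enrolled"],
                    unassigned=counts["unassigned"],
                    gp_fte=float(d["gp_fte"]),
                    age_band_counts=ages,
                    **covs,
                )
            )
        return cls.from_records(records, level=level, provenance=provenance)


def read_panel(path: str | Path, level: str = "unit") -> Panel:
    """Read a coverage panel from CSV, validating every record.

    Raises :class:`SchemaError` for missing required columns,
    :class:`PanelValidationError` naming (unit_id, year) for invariant
    violations and :class:`DuplicateRecordError` for repeated keys.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"unit_id": str, "region_id": str}, float_precision="round_trip"
    )
    if df.empty and not set(REQUIRED_COLUMNS) <= set(df.columns):
        raise SchemaError(
            f"missing required column(s) "
            f"{sorted(set(REQUIRED_COLUMNS) - set(df.columns))} in {path}"
        )
    return Panel.from_dataframe(df, level=level, provenance=str(path))


def write_panel(panel: Panel, path: str | Path) -> Path:
    """Write a panel to CSV so that ``read_panel`` round-trips it exactly.

    Counts are written as integers and ``gp_fte`` at full float precision
    (shortest round-tripping decimal representation).
    """
    path = Path(path)
    df = panel.to_dataframe()
    if df.empty:
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    # repr() is the shortest decimal form that round-trips the float exactly
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    return path


# -- crosswalk --------------------------------------------------------------


@dataclass(frozen=True)
class UnitCrosswalk:
    """Many-to-one map from pre-reorganisation unit ids to current ids.

    Each old id carries an ``effective_year``: records strictly before that
    year are renamed (and merged with any siblings mapping to the same new
    id). In years before the latest effective year, every unit id must be
    either an old id or a current id, otherwise the mapping is incomplete.
    """

    mapping: Mapping[str, tuple[str, int]]

    @classmethod
    def from_csv(cls, path: str | Path) -> "UnitCrosswalk":
        df = pd.read_csv(path, dtype={"old_unit_id": str, "new_unit_id": str})
        for col in ("old_unit_id", "new_unit_id", "effective_year"):
            if col not in df.columns:
                raise SchemaError(f"crosswalk missing required column {col!r}")
        if df["old_unit_id"].duplicated().any():
            dup = df.loc[df["old_unit_id"].duplicated(), "old_unit_id"].iloc[0]
            raise CrosswalkError(f"old unit id {dup!r} maps to more than one new id")
        return cls(
            mapping={
                r.old_unit_id: (r.new_unit_id, int(r.effective_year))
                for r in df.itertuples()
            }
        )

    @classmethod
    def identity(cls) -> "UnitCrosswalk":
        return cls(mapping={})


def _weighted_mean(pairs: list[tuple[float, int]]) -> float | None:
    """Enrolled-weighted mean over (value, weight); None when no values."""
    if not pairs:
        return None
    w = sum(p[1] for p in pairs)
    if w == 0:
        return float(np.mean([p[0] for p in pairs]))
    return sum(v * n for v, n in pairs) / w


def _merge_records(unit_id: str, year: int, group: list[UnitYearRecord]) -> UnitYearRecord:
    region = max(group, key=lambda r: r.enrolled).region_id
    ages = None
    if all(r.age_band_counts is not None for r in group):
        ages = {}
        for r in group:
            for band, c in r.age_band_counts.items():  # type: ignore[union-attr]
                ages[band] = ages.get(band, 0) + c
    covs = {}
    for c in COVARIATE_COLUMNS:
        covs[c] = _weighted_mean(
            [(getattr(r, c), r.enrolled) for r in group if getattr(r, c) is not None]
        )
    merged = UnitYearRecord(
        unit_id=unit_id,
        region_id=region,
        year=year,
        enrolled=sum(r.enrolled for r in group),
        unassigned=sum(r.unassigned for r in group),
        gp_fte=float(sum(r.gp_fte for r in group)),
        age_band_counts=ages,
        **covs,
    )
    merged.validate()
    return merged


def apply_crosswalk(panel: Panel, crosswalk: UnitCrosswalk) -> Panel:
    """Harmonise unit ids across an administrative reorganisation.

    Records in covered years are renamed old → new and merged additively
    (counts and FTE summed, age bands summed, covariates combined as
    enrolled-weighted means). National totals are preserved for every year.
    """
    if not crosswalk.mapping:
        return Panel(records=dict(panel.records), level=panel.level,
                     provenance=panel.provenance)
    boundary = max(eff for _, eff in crosswalk.mapping.values())
    known = set(crosswalk.mapping) | {new for new, _ in crosswalk.mapping.values()}
    renamed: dict[tuple[str, int], list[UnitYearRecord]] = {}
    for rec in panel:
        entry = crosswalk.mapping.get(rec.unit_id)
        if entry is not None and rec.year < entry[1]:
            new_id = entry[0]
        else:
            if rec.year < boundary and rec.unit_id not in known:
                raise CrosswalkError(
                    f"unit {rec.unit_id!r} in covered year {rec.year} is not in "
                    "the crosswalk"
                )
            new_id = rec.unit_id
        renamed.setdefault((new_id, rec.year), []).append(rec)
    out = []
    for (unit_id, year), group in renamed.items():
        if len(group) == 1 and group[0].unit_id == unit_id:
            out.append(group[0])
        else:
            out.append(_merge_records(unit_id, year, group))
    return Panel.from_records(out, level=panel.level,
                              provenance=f"{panel.provenance} [crosswalked]")


def aggregate_panel(panel: Panel, target_level: str) -> Panel:
    """Aggregate a panel to region or national level.

    Counts, FTE and age bands are summed; covariates are combined as
    enrolled-weighted means. The aggregate patient-to-GP ratio is therefore
    total assigned over total FTE, not a mean of unit ratios.
    """
    if target_level not in ("region", "national"):
        raise ValueError(f"target_level must be 'region' or 'national', got {target_level!r}")
    if panel.level == "national" or panel.level == target_level:
        warnings.warn(
            f"panel already at level {panel.level!r}; aggregation is a no-op",
            stacklevel=2,
        )
        return Panel(records=dict(panel.records), level=panel.level,
                     provenance=panel.provenance)
    if len(panel) == 0:
        return Panel(records={}, level=target_level, provenance=panel.provenance)

    groups: dict[tuple[str, int], list[UnitYearRecord]] = {}
    for rec in panel:
        gid = rec.region_id if target_level == "region" else NATIONAL_ID
        groups.setdefault((gid, rec.year), []).append(rec)
    out = []
    for (gid, year), group in groups.items():
        merged = _merge_records(gid, year, group)
        out.append(replace(merged, region_id=gid))
    return Panel.from_records(out, level=target_level, provenance=panel.provenance)
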