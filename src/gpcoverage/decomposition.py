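"""Three-way decomposition of changes in unassigned patients.

With n enrolled patients, GP full-time-equivalent physicians and
patient-to-GP ratio L = (n − m)/GP, the number of patients without an
assigned GP satisfies the accounting identity m = n − GP·L. The change in
m between two periods 0 and 1 splits exactly into three signed effects:

    m(1) − m(0) =  [n(1) − n(0)]                  (demand)
                 − [(GP(1) − GP(0)) · L(0)]       (supply)
                 − [(L(1) − L(0)) · GP(1)]        (productivity)

This is one of several exact allocations of the GP·L cross term; the
default (``list``) evaluates the supply effect at the baseline list ratio
and the productivity effect at the final workforce, i.e. the cross term is
carried by the list dimension. The ``gp`` convention swaps the evaluation
points; ``symmetric`` averages the two. All three preserve the exact-sum
identity and yield the same total change.

Signs are contributions to the change in *unassigned* patients: positive
means more patients without a GP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    DegenerateDecompositionError,
    EmptyResultError,
    UndefinedSharesError,
    YearGapError,
)
from .panel_io import Panel, UnitYearRecord

ALLOCATIONS = ("list", "gp", "symmetric")

#: Relative tolerance for the exact-sum identity check.
IDENTITY_RTOL = 1e-9


@dataclass(frozen=True)
class EffectShares:
    """Unsigned percentage shares (summing to 100) plus the effects' signs."""

    demand: float
    supply: float
    productivity: float
    signs: tuple[int, int, int]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.demand, self.supply, self.productivity)


@dataclass(frozen=True)
class DecompositionResult:
    """Signed demand/supply/productivity contributions to Δm over a period."""

    scope: str
    year_0: int
    year_1: int
    total_change: float
    demand_effect: float
    supply_effect: float
    productivity_effect: float
    allocation: str
    baseline_unassigned: int

    @property
    def period(self) -> tuple[int, int]:
        return (self.year_0, self.year_1)

    @property
    def identity_residual(self) -> float:
        """Absolute gap between the effect sum and the recomputed Δm."""
        return abs(
            self.demand_effect + self.supply_effect + self.productivity_effect
            - self.total_change
        )

    def shares(self) -> EffectShares:
        return relative_shares(self)


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def decompose(
    rec0: UnitYearRecord,
    rec1: UnitYearRecord,
    allocation: str = "list",
) -> DecompositionResult:
    """Decompose the change in unassigned patients between two records.

    The records must describe the same scope (unit or aggregate) and both
    must have gp_fte > 0, otherwise the list ratio is undefined and the
    decomposition is degenerate. Any ordered pair of periods is accepted.
    """
    if allocation not in ALLOCATIONS:
        raise ValueError(f"allocation must be one of {ALLOCATIONS}, got {allocation!r}")
    if rec0.unit_id != rec1.unit_id:
        raise ValueError(
            f"scope mismatch: {rec0.unit_id!r} vs {rec1.unit_id!r}"
        )
    for rec in (rec0, rec1):
        if rec.gp_fte == 0:
            raise DegenerateDecompositionError(
                f"(unit_id={rec.unit_id!r}, year={rec.year}): gp_fte = 0, "
                "patient-to-GP ratio undefined"
            )
    n0, n1 = rec0.enrolled, rec1.enrolled
    m0, m1 = rec0.unassigned, rec1.unassigned
    gp0, gp1 = rec0.gp_fte, rec1.gp_fte
    l0 = (n0 - m0) / gp0
    l1 = (n1 - m1) / gp1

    demand = float(n1 - n0)
    if allocation == "list":
        supply = -(gp1 - gp0) * l0
        productivity = -(l1 - l0) * gp1
    elif allocation == "gp":
        supply = -(gp1 - gp0) * l1
        productivity = -(l1 - l0) * gp0
    else:  # symmetric: average of the two exact allocations
        supply = -(gp1 - gp0) * (l0 + l1) / 2.0
        productivity = -(l1 - l0) * (gp0 + gp1) / 2.0

    total = float(m1 - m0)
    result = DecompositionResult(
        scope=rec0.unit_id,
        year_0=rec0.year,
        year_1=rec1.year,
        total_change=total,
        demand_effect=demand,
        supply_effect=supply,
        productivity_effect=productivity,
        allocation=allocation,
        baseline_unassigned=m0,
    )
    scale = max(abs(total), abs(demand), abs(supply), abs(productivity), 1.0)
    if result.identity_residual > IDENTITY_RTOL * scale:
        raise AssertionError(
            f"decomposition identity violated for {rec0.unit_id!r} "
            f"{rec0.year}->{rec1.year}: residual {result.identity_residual}"
        )
    return result


def chain_decompose(
    series: Sequence[UnitYearRecord] | Iterable[UnitYearRecord],
    allocation: str = "list",
    allow_gaps: bool = False,
) -> list[DecompositionResult]:
    """Yearly decomposition along a single scope's time series.

    Returns one result per adjacent year pair. The yearly total changes
    telescope exactly to m(last) − m(first), and the yearly demand effects
    to n(last) − n(first); supply and productivity chains are path
    dependent and need not match the single-step long-run decomposition.
    """
    recs = sorted(series, key=lambda r: r.year)
    if len(recs) < 2:
        raise ValueError("chain_decompose needs at least two records")
    scopes = {r.unit_id for r in recs}
    if len(scopes) > 1:
        raise ValueError(f"series mixes scopes: {sorted(scopes)}")
    years = [r.year for r in recs]
    if len(set(years)) != len(years):
        raise ValueError("series has duplicate years")
    gaps = [
        (a, b) for a, b in zip(years, years[1:]) if b != a + 1
    ]
    if gaps and not allow_gaps:
        raise YearGapError(
            f"missing years between {gaps[0][0]} and {gaps[0][1]}; "
            "pass allow_gaps=True to chain adjacent-available pairs"
        )
    if gaps:
        warnings.warn(f"year gaps bridged by adjacent-available pairs: {gaps}",
                      stacklevel=2)
    return [decompose(a, b, allocation) for a, b in zip(recs, recs[1:])]


def relative_shares(result: DecompositionResult) -> EffectShares:
    """Percentage shares |effect|/Σ|effects|·100, summing to 100 exactly.

    Signs are carried as metadata (mixed-sign effects would make signed
    shares exceed 100). The productivity share is set by complement so the
    three floats add to exactly 100.
    """
    effects = (result.demand_effect, result.supply_effect, result.productivity_effect)
    denom = sum(abs(e) for e in effects)
    if denom == 0:
        raise UndefinedSharesError(
            f"all three effects are zero for {result.scope!r} "
            f"{result.year_0}->{result.year_1}"
        )
    demand = abs(effects[0]) / denom * 100.0
    supply = abs(effects[1]) / denom * 100.0
    return EffectShares(
        demand=demand,
        supply=supply,
        productivity=100.0 - demand - supply,
        signs=tuple(_sign(e) for e in effects),  # type: ignore[arg-type]
    )


@dataclass
class ShareTable:
    """Per-scope decomposition table with percentage shares.

    Rows are ordered from the largest increase to the largest reduction in
    the percent of patients without a GP over the period (each scope's own
    enrolled denominator per year), matching how per-unit results are
    conventionally displayed. Absolute shares sum to 100 per row.
    """

    table: pd.DataFrame
    allocation: str
    period: tuple[int, int]

    COLUMNS = (
        "scope", "year_0", "year_1", "total_change",
        "demand_effect", "supply_effect", "productivity_effect",
        "demand_share", "supply_share", "productivity_share",
        "pct_unassigned_change", "allocation",
    )

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def decompose_all(
    panel: Panel,
    year_0: int,
    year_1: int,
    allocation: str = "list",
) -> ShareTable:
    """Decompose every scope in a panel between two years.

    Scopes missing either year (or with gp_fte = 0 at an endpoint) are
    dropped with a warning; an empty result raises
    :class:`EmptyResultError`.
    """
    rows = []
    skipped = []
    for unit in panel.units():
        rec0 = panel.get(unit, year_0)
        rec1 = panel.get(unit, year_1)
        if rec0 is None or rec1 is None:
            skipped.append(unit)
            continue
        try:
            res = decompose(rec0, rec1, allocation)
        except DegenerateDecompositionError:
            skipped.append(unit)
            continue
        shares = relative_shares(res)
        ordering = rec1.unassigned / rec1.enrolled - rec0.unassigned / rec0.enrolled
        rows.append(
            {
                "scope": unit,
                "year_0": year_0,
                "year_1": year_1,
                "total_change": res.total_change,
                "demand_effect": res.demand_effect,
                "supply_effect": res.supply_effect,
                "productivity_effect": res.productivity_effect,
                "demand_share": shares.demand,
                "supply_share": shares.supply,
                "productivity_share": shares.productivity,
                "pct_unassigned_change": ordering,
                "allocation": allocation,
            }
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} scope(s) dropped (missing year or zero FTE): "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}",
            stacklevel=2,
        )
    if not rows:
        raise EmptyResultError(
            f"no scope has usable records for both {year_0} and {year_1}"
        )
    df = pd.DataFrame(rows, columns=list(ShareTable.COLUMNS))
    df = df.sort_values(
        "pct_unassigned_change", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return ShareTable(table=df, allocation=allocation, period=(year_0, year_1))
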