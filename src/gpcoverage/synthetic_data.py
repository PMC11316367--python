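"""Synthetic unit-by-year coverage panels with configurable trends.

The generator emulates the statistical structure of the Portuguese
primary-care administrative series 2009–2023: ~55 units, a national
enrolment of ~11.3 million patients in 2009 that declines through 2016
(including an abrupt 2012–2013 administrative purge of non-users) and then
grows again, a GP FTE workforce that falls to 2014, recovers to 2018 and
falls again in 2021–2022, a slow downward drift in the average list size,
an ageing case-mix, and unit-level contextual covariates (elderly share,
diabetes prevalence, population density) weakly-to-moderately negatively
correlated with the patient-to-GP ratio.

Unassigned patients are always *derived* through the accounting identity
m = n − round(GP·L) — never sampled — so the decomposition identity holds
exactly on every generated record. All randomness flows through a single
numpy Generator seeded from the config.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import FeasibilityError
from .panel_io import Panel, UnitYearRecord
from .workforce import PhysicianRecord

BAND_LABELS = ("0_6", "7_64", "65_74", "75p")

#: National enrolment path anchors relative to the first year (purge excluded):
#: gentle decline to 2016, symmetric recovery to 2023.
DEFAULT_DEMAND_ANCHORS = {2009: 1.0, 2016: 0.972, 2023: 1.0}

#: GP FTE path anchors relative to the first year: decline to 2014, recovery
#: to 2018, a dip in 2019, renewed decline in 2021–2022, hiring in 2023;
#: endpoint matches the published 5 650 → 5 395 FTE (−4.5%).
DEFAULT_SUPPLY_ANCHORS = {
    2009: 1.0, 2014: 0.940, 2018: 0.985, 2019: 0.980,
    2020: 0.985, 2022: 0.947, 2023: 0.9549,
}

#: Age-mix endpoints: shares of the 0–6, 65–74 and 75+ bands chosen so the
#: weighted units per patient are 1.24 in the first year and 1.32 in the last.
DEFAULT_AGE_SHARES_START = {"0_6": 0.070, "65_74": 0.105, "75p": 0.0667}
DEFAULT_AGE_SHARES_END = {"0_6": 0.060, "65_74": 0.115, "75p": 0.1167}

#: Attenuation compensation for the copula correlations: within-unit
#: temporal variation in the realized list ratio dilutes the unit-level
#: latent correlation by roughly this factor under default settings.
_CORR_ATTENUATION = 0.95


class ScenarioConfig(BaseModel):
    """Full parameterisation of the synthetic panel generator."""

    model_config = ConfigDict(validate_assignment=True)

    seed: int
    n_units: int = Field(default=55, ge=1)
    n_regions: int = Field(default=5, ge=1)
    year_start: int = 2009
    year_end: int = 2023

    national_enrolled_start: float = Field(default=11_293_000, gt=0)
    unit_size_sigma: float = Field(default=0.5, ge=0)

    baseline_unassigned_share: float = Field(default=0.158, ge=0.0, lt=1.0)
    unassigned_share_sd: float = Field(default=0.05, ge=0)

    demand_anchors: dict[int, float] = Field(
        default_factory=lambda: dict(DEFAULT_DEMAND_ANCHORS)
    )
    purge_years: tuple[int, int] | None = (2012, 2013)
    purge_fraction: float = Field(default=0.07, ge=0.0, lt=1.0)

    supply_anchors: dict[int, float] = Field(
        default_factory=lambda: dict(DEFAULT_SUPPLY_ANCHORS)
    )

    list_ratio_start: float = Field(default=1680.0, gt=0)
    list_sigma: float = Field(default=0.08, ge=0)
    list_drift_per_year: float = Field(default=-0.003, gt=-1.0)

    noise_sd: float = Field(default=0.02, ge=0)
    #: fraction of the noise SD that is transient (iid per unit-year); the
    #: remainder is a persistent per-unit level offset.
    noise_transient_frac: float = Field(default=0.1, ge=0.0, le=1.0)

    corr_elderly: float = Field(default=-0.40, ge=-1.0, le=1.0)
    corr_diabetes: float = Field(default=-0.40, ge=-1.0, le=1.0)
    corr_density: float = Field(default=-0.15, ge=-1.0, le=1.0)
    diabetes_mean: float = Field(default=0.075, gt=0, lt=1)
    density_median: float = Field(default=300.0, gt=0)
    density_sigma: float = Field(default=0.5, ge=0)

    age_shares_start: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_AGE_SHARES_START)
    )
    age_shares_end: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_AGE_SHARES_END)
    )

    #: exact-arithmetic switches used by single-driver scenarios
    fte_integer: bool = False
    list_integer: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.year_end - self.year_start < 1:
            raise FeasibilityError("years must span at least 2 calendar years")
        for name, anchors in (("demand", self.demand_anchors),
                              ("supply", self.supply_anchors)):
            if any(v <= 0 for v in anchors.values()):
                raise FeasibilityError(f"{name} multipliers must be positive")
        for shares in (self.age_shares_start, self.age_shares_end):
            if set(shares) != set(BAND_LABELS) - {"7_64"}:
                raise FeasibilityError(
                    f"age shares must specify bands {sorted(set(BAND_LABELS) - {'7_64'})}"
                )
            if any(s < 0 for s in shares.values()) or sum(shares.values()) >= 0.8:
                raise FeasibilityError("age shares infeasible (negative or too large)")
        horizon = self.year_end - self.year_start
        if (1.0 + self.list_drift_per_year) ** horizon * self.list_ratio_start <= 0:
            raise FeasibilityError("list drift drives the list ratio to zero")
        if self.noise_sd >= 0.5:
            raise FeasibilityError("noise_sd >= 0.5 makes counts unreliable")
        return self

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @classmethod
    def flat(cls, seed: int, **overrides) -> "ScenarioConfig":
        """A steady-state scenario: no trends, no purge, no drift, no noise."""
        base: dict = dict(
            seed=seed,
            demand_anchors={},
            purge_fraction=0.0,
            purge_years=None,
            supply_anchors={},
            list_drift_per_year=0.0,
            noise_sd=0.0,
            age_shares_end=dict(DEFAULT_AGE_SHARES_START),
        )
        base.update(overrides)
        return cls(**base)


def piecewise_path(anchors: dict[int, float], years: list[int]) -> np.ndarray:
    """Piecewise-linear interpolation of anchor multipliers over the years.

    Missing edges are held flat; an empty anchor dict gives all ones.
    """
    if not anchors:
        return np.ones(len(years))
    xs = np.array(sorted(anchors))
    ys = np.array([anchors[x] for x in xs], dtype=float)
    return np.interp(np.array(years, dtype=float), xs, ys)


def _purge_path(config: ScenarioConfig) -> np.ndarray:
    """Cumulative multiplier of the one-off enrolment purge per year."""
    years = np.array(config.years)
    if config.purge_years is None or config.purge_fraction == 0:
        return np.ones(len(years))
    y0, y1 = config.purge_years
    k_total = y1 - y0 + 1
    k_done = np.clip(years - y0 + 1, 0, k_total)
    return (1.0 - config.purge_fraction) ** (k_done / k_total)


def demand_path(config: ScenarioConfig) -> np.ndarray:
    """National enrolment multiplier per year (trend × purge)."""
    return piecewise_path(config.demand_anchors, config.years) * _purge_path(config)


def supply_path(config: ScenarioConfig) -> np.ndarray:
    return piecewise_path(config.supply_anchors, config.years)


def list_path(config: ScenarioConfig) -> np.ndarray:
    t = np.arange(len(config.years), dtype=float)
    return (1.0 + config.list_drift_per_year) ** t


def configured_effect_signs(config: ScenarioConfig) -> dict[str, np.ndarray]:
    """Expected sign of each yearly national effect, from the config alone.

    Demand effect sign follows the yearly change of the enrolment path;
    supply and productivity effects are contributions to *unassigned*
    patients, so their signs are the negated changes of the FTE and list
    paths. Zero marks years where the configured path is flat.
    """
    dm, sm, lm = demand_path(config), supply_path(config), list_path(config)
    return {
        "demand": np.sign(np.diff(dm)),
        "supply": -np.sign(np.diff(sm)),
        "productivity": -np.sign(np.diff(lm)),
    }


def _apportion(total: int, shares: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of an integer total across shares."""
    shares = np.asarray(shares, dtype=float)
    shares = shares / shares.sum()
    raw = shares * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _age_share_paths(config: ScenarioConfig) -> dict[str, np.ndarray]:
    n_years = len(config.years)
    frac = (np.arange(n_years) / (n_years - 1)) if n_years > 1 else np.zeros(1)
    paths = {}
    for band in ("0_6", "65_74", "75p"):
        s0 = config.age_shares_start[band]
        s1 = config.age_shares_end[band]
        paths[band] = s0 + (s1 - s0) * frac
    return paths


def generate_panel(config: ScenarioConfig) -> Panel:
    """Generate a unit-level coverage panel under the configured scenario.

    The same config (including seed) always produces a bit-identical
    panel. Unit baseline sizes are log-normal across units, scaled so
    national enrolment in the first year is approximately the configured
    total. Unassigned counts are derived from n, GP and the target list
    ratio and clipped into [0, n]; the implied list ratio absorbs the
    rounding residue so the identity m = n − GP·L stays exact.
    """
    rng = np.random.default_rng(config.seed)
    years = config.years
    n_units = config.n_units

    unit_ids = [f"U{i + 1:03d}" for i in range(n_units)]
    region_ids = [f"R{(i * config.n_regions) // n_units + 1}" for i in range(n_units)]

    size_raw = rng.lognormal(mean=0.0, sigma=config.unit_size_sigma, size=n_units)
    n_base = size_raw / size_raw.sum() * config.national_enrolled_start

    b_u = np.clip(
        rng.normal(config.baseline_unassigned_share, config.unassigned_share_sd, n_units),
        0.03, 0.45,
    )

    z_list = rng.standard_normal(n_units)
    l_base = config.list_ratio_start * np.exp(config.list_sigma * z_list)
    if config.list_integer:
        l_base = np.maximum(np.round(l_base), 1.0)
    gp_base = n_base * (1.0 - b_u) / l_base
    if config.fte_integer:
        gp_base = np.maximum(np.round(gp_base), 1.0)

    # Unit-level latent covariates via a Gaussian copula against z_list.
    # The noise component is residualised against z_list and re-standardised
    # (Gram-Schmidt), so the latent *sample* correlation hits the target
    # exactly rather than up to O(1/sqrt(n_units)) sampling error; the
    # achieved panel correlation then deviates only through the monotone
    # covariate transforms and within-unit temporal variation.
    def _standardize(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    z_list_std = _standardize(z_list)

    def _copula(target: float) -> np.ndarray:
        rho = float(np.clip(target / _CORR_ATTENUATION, -0.99, 0.99))
        eps = rng.standard_normal(n_units)
        if n_units < 3 or z_list_std.std() == 0:
            return rho * z_list_std + np.sqrt(1.0 - rho * rho) * eps
        resid = eps - (eps @ z_list_std) / (z_list_std @ z_list_std) * z_list_std
        return rho * z_list_std + np.sqrt(1.0 - rho * rho) * _standardize(resid)

    z_elderly = _copula(config.corr_elderly)
    z_diab = _copula(config.corr_diabetes)
    z_dens = _copula(config.corr_density)
    elderly_tilt = np.clip(1.0 + 0.2 * z_elderly, 0.4, 1.8)
    diabetes_u = np.clip(config.diabetes_mean * (1.0 + 0.25 * z_diab), 0.01, 0.30)
    density_u = config.density_median * np.exp(config.density_sigma * z_dens)

    # noise: persistent per-unit offsets plus a small transient component
    sd_pers = config.noise_sd * (1.0 - config.noise_transient_frac)
    sd_trans = config.noise_sd * config.noise_transient_frac
    n_years = len(years)

    def _noise_factors() -> np.ndarray:
        pers = rng.normal(0.0, sd_pers, n_units) if sd_pers > 0 else np.zeros(n_units)
        trans = (
            rng.normal(0.0, sd_trans, (n_units, n_years))
            if sd_trans > 0 else np.zeros((n_units, n_years))
        )
        return np.clip((1.0 + pers)[:, None] * (1.0 + trans), 0.05, None)

    f_n, f_gp, f_l = _noise_factors(), _noise_factors(), _noise_factors()

    dm, sm, lm = demand_path(config), supply_path(config), list_path(config)
    age_paths = _age_share_paths(config)

    records = []
    for i in range(n_units):
        for t, year in enumerate(years):
            n_t = int(np.round(n_base[i] * dm[t] * f_n[i, t]))
            gp_t = gp_base[i] * sm[t] * f_gp[i, t]
            if config.fte_integer:
                gp_t = max(1.0, float(np.round(gp_t)))
            l_t = l_base[i] * lm[t] * f_l[i, t]
            assigned = int(np.round(gp_t * l_t))
            assigned = min(max(assigned, 0), n_t)
            m_t = n_t - assigned

            s_child = age_paths["0_6"][t]
            s_6574 = age_paths["65_74"][t] * elderly_tilt[i]
            s_75p = age_paths["75p"][t] * elderly_tilt[i]
            s_mid = 1.0 - s_child - s_6574 - s_75p
            counts = _apportion(n_t, np.array([s_child, s_mid, s_6574, s_75p]))
            ages = {
                "0_6": int(counts[0]),
                "7_64": int(counts[1]),
                "65_74": int(counts[2]),
                "75p": int(counts[3]),
            }
            elderly_share = (ages["65_74"] + ages["75p"]) / n_t if n_t else 0.0

            records.append(
                UnitYearRecord(
                    unit_id=unit_ids[i],
                    region_id=region_ids[i],
                    year=year,
                    enrolled=n_t,
                    unassigned=m_t,
                    gp_fte=float(gp_t),
                    elderly_share=float(elderly_share),
                    diabetes_prevalence=float(diabetes_u[i]),
                    population_density=float(density_u[i]),
                    age_band_counts=ages,
                )
            )
    return Panel.from_records(
        records, level="unit", provenance=f"synthetic(seed={config.seed})"
    )


def generate_roster(
    unit_record: UnitYearRecord,
    mean_hours: float = 40.0,
    hours_dispersion: float = 0.15,
    seed: int = 0,
) -> list[PhysicianRecord]:
    """Generate a physician roster consistent with one unit-year record.

    The roster's total FTE matches the record's gp_fte to within 0.5%
    (hours are rescaled exactly onto the target) and list sizes are
    apportioned by largest remainder so Σ list_size equals the record's
    assigned patients exactly.
    """
    if unit_record.gp_fte <= 0:
        raise FeasibilityError(
            f"unit {unit_record.unit_id!r} has gp_fte = {unit_record.gp_fte}; "
            "no roster can be generated"
        )
    rng = np.random.default_rng(seed)
    n_phys = int(np.round(unit_record.gp_fte / (mean_hours / 40.0)))
    if n_phys < 1:
        raise FeasibilityError(
            f"gp_fte = {unit_record.gp_fte} with mean_hours = {mean_hours} "
            "implies zero physicians"
        )
    hours_raw = np.clip(
        mean_hours * (1.0 + hours_dispersion * rng.standard_normal(n_phys)),
        4.0, None,
    )
    hours = hours_raw * (unit_record.gp_fte * 40.0 / hours_raw.sum())
    lists = _apportion(unit_record.assigned, hours)
    return [
        PhysicianRecord(
            physician_id=f"{unit_record.unit_id}-P{k + 1:03d}",
            unit_id=unit_record.unit_id,
            weekly_hours=float(hours[k]),
            list_size=int(lists[k]),
        )
        for k in range(n_phys)
    ]


Driver = Literal["demand", "supply", "productivity"]


def scenario_single_driver(base: ScenarioConfig, driver: Driver) -> ScenarioConfig:
    """A scenario in which only one driver's trend is active.

    Noise and cross-unit unassigned-share dispersion are switched off and
    the other two drivers are held flat, so a decomposition of the
    generated panel attributes 100% of every change to the named driver
    and exactly 0 to the others. The supply scenario additionally snaps
    FTE and target list sizes to integers so the implied list ratio is
    bitwise constant across years.
    """
    common: dict = dict(
        noise_sd=0.0,
        unassigned_share_sd=0.0,
        age_shares_end=dict(base.age_shares_start),
    )
    if driver == "demand":
        updates = dict(common, supply_anchors={}, list_drift_per_year=0.0)
    elif driver == "supply":
        updates = dict(
            common,
            demand_anchors={}, purge_fraction=0.0, purge_years=None,
            list_drift_per_year=0.0,
            fte_integer=True, list_integer=True,
        )
    elif driver == "productivity":
        updates = dict(
            common,
            demand_anchors={}, purge_fraction=0.0, purge_years=None,
            supply_anchors={},
        )
    else:
        raise ValueError(f"unknown driver {driver!r}")
    return base.model_copy(update=updates)
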