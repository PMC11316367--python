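import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcoverage import (
    ALLOCATIONS,
    Panel,
    ScenarioConfig,
    UnitYearRecord,
    aggregate_panel,
    chain_decompose,
    decompose,
    decompose_all,
    generate_panel,
    relative_shares,
)
from gpcoverage.decomposition import DecompositionResult
from gpcoverage.errors import (
    DegenerateDecompositionError,
    EmptyResultError,
    UndefinedSharesError,
    YearGapError,
)


def _rec(year, n, m, gp, unit="X"):
    return UnitYearRecord(unit, "R1", year, n, m, gp)


record_pairs = st.tuples(
    st.integers(1, 5_000_000),  # n0
    st.floats(0.0, 1.0),  # m0 fraction
    st.floats(0.01, 20_000.0),  # gp0
    st.integers(1, 5_000_000),  # n1
    st.floats(0.0, 1.0),  # m1 fraction
    st.floats(0.01, 20_000.0),  # gp1
).map(
    lambda t: (
        _rec(2009, t[0], int(t[0] * t[1]), t[2]),
        _rec(2023, t[3], int(t[3] * t[4]), t[5]),
    )
)


class TestDecompose:
    def test_national_2009_2023_worked_example(self, national_records):
        """Printed aggregates: demand -793k, supply ~ +428k, productivity
        ~ +265k, total -100k (1.8M -> 1.7M unassigned)."""
        res = decompose(*national_records)
        assert res.demand_effect == -793_000
        assert res.supply_effect == pytest.approx(428_445, abs=1)
        assert res.productivity_effect == pytest.approx(264_555, abs=1)
        assert res.total_change == -100_000
        assert res.baseline_unassigned == 1_800_000

    def test_no_change_gives_all_zero(self):
        r = _rec(2009, 1000, 100, 3.0)
        res = decompose(r, _rec(2023, 1000, 100, 3.0))
        assert (res.demand_effect, res.supply_effect, res.productivity_effect) == (0, 0, 0)
        assert res.total_change == 0

    def test_offsetting_supply_and_productivity(self):
        # L falls 300 -> 225 exactly as FTE rises 3 -> 4; m unchanged
        res = decompose(_rec(2009, 1000, 100, 3.0), _rec(2023, 1000, 100, 4.0))
        assert res.demand_effect == 0
        assert res.supply_effect == -300
        assert res.productivity_effect == 300
        assert res.total_change == 0

    def test_zero_fte_endpoint_is_degenerate(self):
        with pytest.raises(DegenerateDecompositionError):
            decompose(_rec(2009, 100, 100, 0.0), _rec(2023, 100, 10, 1.0))

    def test_scope_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            decompose(_rec(2009, 100, 10, 1.0, unit="A"),
                      _rec(2023, 100, 10, 1.0, unit="B"))

    def test_reversed_period_negates_demand_and_total(self, national_records):
        fwd = decompose(*national_records)
        rev = decompose(national_records[1], national_records[0])
        assert rev.total_change == -fwd.total_change
        assert rev.demand_effect == -fwd.demand_effect

    @settings(deadline=None, max_examples=200)
    @given(pair=record_pairs, allocation=st.sampled_from(ALLOCATIONS))
    def test_exact_sum_identity(self, pair, allocation):
        """Effects sum to the recomputed change in unassigned patients for
        every allocation convention."""
        res = decompose(*pair, allocation=allocation)
        scale = max(abs(res.total_change), abs(res.demand_effect),
                    abs(res.supply_effect), abs(res.productivity_effect), 1.0)
        assert res.identity_residual <= 1e-9 * scale

    @settings(deadline=None, max_examples=100)
    @given(pair=record_pairs)
    def test_total_is_convention_invariant(self, pair):
        totals = {decompose(*pair, allocation=a).total_change for a in ALLOCATIONS}
        assert len(totals) == 1

    def test_symmetric_is_average_of_list_and_gp(self, national_records):
        by = {a: decompose(*national_records, allocation=a) for a in ALLOCATIONS}
        assert by["symmetric"].supply_effect == pytest.approx(
            (by["list"].supply_effect + by["gp"].supply_effect) / 2
        )
        assert by["symmetric"].productivity_effect == pytest.approx(
            (by["list"].productivity_effect + by["gp"].productivity_effect) / 2
        )


class TestChainDecompose:
    def test_yearly_totals_telescope(self):
        series = [_rec(2009, 1000, 100, 3.0), _rec(2010, 1050, 120, 3.0),
                  _rec(2011, 980, 90, 3.1)]
        chain = chain_decompose(series)
        assert [r.total_change for r in chain] == [20, -30]
        assert sum(r.total_change for r in chain) == 90 - 100

    def test_demand_effects_telescope_to_long_run(self):
        series = [_rec(2009 + t, 1000 + 37 * t, 100 + t, 2.0 + 0.1 * t)
                  for t in range(6)]
        chain = chain_decompose(series)
        assert sum(r.demand_effect for r in chain) == series[-1].enrolled - series[0].enrolled

    def test_each_step_matches_single_pair_decomposition(self):
        series = [_rec(2009, 1000, 200, 2.0), _rec(2010, 1000, 120, 2.2),
                  _rec(2011, 1100, 220, 2.2)]
        chain = chain_decompose(series)
        for step, (a, b) in zip(chain, zip(series, series[1:])):
            single = decompose(a, b)
            assert step == single

    def test_year_gap_raises_unless_allowed(self):
        series = [_rec(2009, 1000, 100, 2.0), _rec(2012, 900, 90, 2.0)]
        with pytest.raises(YearGapError):
            chain_decompose(series)
        with pytest.warns(UserWarning, match="gap"):
            chain = chain_decompose(series, allow_gaps=True)
        assert len(chain) == 1

    @settings(deadline=None, max_examples=50)
    @given(
        ns=st.lists(st.integers(100, 100_000), min_size=15, max_size=15),
        fracs=st.lists(st.floats(0.0, 0.9), min_size=15, max_size=15),
        gps=st.lists(st.floats(0.5, 500.0), min_size=15, max_size=15),
    )
    def test_telescoping_on_random_15_year_series(self, ns, fracs, gps):
        series = [
            _rec(2009 + t, ns[t], int(ns[t] * fracs[t]), gps[t]) for t in range(15)
        ]
        chain = chain_decompose(series)
        telescoped = sum(r.total_change for r in chain)
        assert telescoped == series[-1].unassigned - series[0].unassigned
        assert sum(r.demand_effect for r in chain) == (
            series[-1].enrolled - series[0].enrolled
        )


class TestRelativeShares:
    def test_national_shares(self, national_records):
        shares = relative_shares(decompose(*national_records))
        assert shares.demand == pytest.approx(53.4, abs=0.05)
        assert shares.supply == pytest.approx(28.8, abs=0.05)
        assert shares.productivity == pytest.approx(17.8, abs=0.05)
        assert shares.signs == (-1, 1, 1)

    @pytest.mark.parametrize(
        "effects,expected",
        [((5, 0, 0), (100, 0, 0)), ((1, 1, 2), (25, 25, 50)),
         ((-2, 1, 1), (50, 25, 25))],
    )
    def test_absolute_value_proportionality(self, effects, expected):
        res = DecompositionResult("X", 2009, 2023, sum(effects), *effects,
                                  allocation="list", baseline_unassigned=0)
        assert relative_shares(res).as_tuple() == pytest.approx(expected)

    def test_shares_sum_to_exactly_100(self):
        res = DecompositionResult("X", 2009, 2023, 0.3, 0.1, 0.1, 0.1,
                                  allocation="list", baseline_unassigned=0)
        assert sum(relative_shares(res).as_tuple()) == 100.0

    def test_all_zero_effects_undefined(self):
        res = DecompositionResult("X", 2009, 2023, 0, 0, 0, 0,
                                  allocation="list", baseline_unassigned=0)
        with pytest.raises(UndefinedSharesError):
            relative_shares(res)


class TestDecomposeAll:
    def test_single_unit_table(self):
        panel = Panel.from_records(
            [_rec(2009, 1000, 100, 2.0, unit="A"), _rec(2023, 900, 150, 1.8, unit="A")]
        )
        table = decompose_all(panel, 2009, 2023).table
        assert len(table) == 1
        row = table.iloc[0]
        assert row.demand_share + row.supply_share + row.productivity_share == 100.0

    def test_ordering_puts_largest_increase_first(self):
        panel = Panel.from_records(
            [
                _rec(2009, 1000, 100, 2.0, unit="worse"),
                _rec(2023, 1000, 300, 1.5, unit="worse"),
                _rec(2009, 1000, 300, 1.5, unit="better"),
                _rec(2023, 1000, 100, 2.0, unit="better"),
            ]
        )
        table = decompose_all(panel, 2009, 2023).table
        assert list(table.scope) == ["worse", "better"]

    def test_rows_match_independent_per_unit_decompositions(self, default_panel):
        units = default_panel.units()[:10]
        sub = Panel.from_records(
            [r for r in default_panel if r.unit_id in units]
        )
        table = decompose_all(sub, 2009, 2023).table
        for row in table.itertuples():
            res = decompose(sub.get(row.scope, 2009), sub.get(row.scope, 2023))
            assert row.demand_effect == res.demand_effect
            assert row.supply_effect == res.supply_effect
            assert row.productivity_effect == res.productivity_effect
            shares = relative_shares(res)
            assert row.demand_share == shares.demand
            assert row.supply_share == shares.supply

    def test_scopes_missing_a_year_dropped_with_warning(self):
        panel = Panel.from_records(
            [
                _rec(2009, 1000, 100, 2.0, unit="A"),
                _rec(2023, 900, 150, 1.8, unit="A"),
                _rec(2009, 500, 50, 1.0, unit="B"),
            ]
        )
        with pytest.warns(UserWarning, match="dropped"):
            table = decompose_all(panel, 2009, 2023).table
        assert list(table.scope) == ["A"]

    def test_no_complete_scope_is_an_error(self):
        panel = Panel.from_records([_rec(2009, 1000, 100, 2.0, unit="A")])
        with pytest.raises(EmptyResultError):
            decompose_all(panel, 2009, 2023)


class TestAggregationInteraction:
    def test_national_total_change_is_sum_of_unit_changes(self, default_panel):
        nat = aggregate_panel(default_panel, "national")
        res = decompose(nat.get("NATIONAL", 2009), nat.get("NATIONAL", 2023))
        unit_sum = sum(
            default_panel.get(u, 2023).unassigned - default_panel.get(u, 2009).unassigned
            for u in default_panel.units()
        )
        assert res.total_change == unit_sum

    def test_effects_on_aggregates_differ_from_summed_unit_effects(self):
        """Effects are not additive across units: a constructed two-unit
        counterexample where pooled and summed decompositions disagree."""
        recs = [
            _rec(2009, 10_000, 1000, 10.0, unit="big"),
            _rec(2023, 9_000, 1500, 8.0, unit="big"),
            _rec(2009, 1_000, 500, 1.0, unit="small"),
            _rec(2023, 1_200, 100, 2.0, unit="small"),
        ]
        panel = Panel.from_records(recs)
        nat = aggregate_panel(panel, "national")
        pooled = decompose(nat.get("NATIONAL", 2009), nat.get("NATIONAL", 2023))
        summed_supply = sum(
            decompose(panel.get(u, 2009), panel.get(u, 2023)).supply_effect
            for u in ("big", "small")
        )
        assert pooled.supply_effect != pytest.approx(summed_supply, rel=1e-6)
        # ... but totals still agree exactly
        assert pooled.total_change == sum(
            decompose(panel.get(u, 2009), panel.get(u, 2023)).total_change
            for u in ("big", "small")
        )


def test_single_driver_scenarios_recover_the_driver():
    """When only one driver moves, it carries 100% of the share and the
    other two effects are exactly zero, for every unit and driver."""
    from gpcoverage import scenario_single_driver

    base = ScenarioConfig(seed=2009, n_units=12)
    effect_of = {
        "demand": "demand_effect",
        "supply": "supply_effect",
        "productivity": "productivity_effect",
    }
    for driver, attr in effect_of.items():
        panel = generate_panel(scenario_single_driver(base, driver))
        for unit in panel.units():
            series = panel.series(unit)
            res = decompose(series[0], series[-1])
            others = [
                getattr(res, a) for a in effect_of.values() if a != attr
            ]
            assert others == [0, 0]
            if getattr(res, attr) != 0:
                shares = relative_shares(res)
                assert getattr(shares, driver) == 100.0
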