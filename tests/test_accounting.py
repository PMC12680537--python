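"""Core biomass-movement arithmetic, aggregation and comparison statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biomove import accounting as acc
from biomove.accounting import GroupNode, SpeciesRecord
from biomove.errors import InvalidArgumentError, UndefinedValueError
from biomove.synthetic import SpeciesTableConfig, gen_species_table
from biomove.uncertain import UncertainValue
from biomove.units import UNITS

GT = UNITS.tonnes_per_gt


def leaf(i, biomass_t, daily_km=None, annual_km=None, activity=None, speed=None,
         mode="walk_run", path=("land",)):
    return SpeciesRecord(
        id=f"sp{i}",
        group_path=path,
        locomotion_mode=mode,
        biomass_t=UncertainValue.exact(biomass_t),
        daily_distance_km=None if daily_km is None else UncertainValue.exact(daily_km),
        annual_distance_km=None if annual_km is None else UncertainValue.exact(annual_km),
        activity_hours_per_day=activity,
        characteristic_speed_km_h=speed,
    )


class TestElementaryOps:
    def test_wild_mammal_headline_product(self):
        # 20 Mt moving 4 km/d -> ~30 Gt km/yr
        assert acc.biomass_movement(2e7, 1460) == pytest.approx(2.92e10)

    def test_zero_biomass(self):
        assert acc.biomass_movement(0.0, 12345.0) == 0.0

    def test_human_headline_product(self):
        # 0.43 Gt at ~30 km/d lands in the printed 4,000 Gt km/yr ballpark
        m = acc.biomass_movement(4.32e8, 10950)
        assert m == pytest.approx(4.7304e12)
        assert acc.round_sigfig(m / GT, 1) == 5000  # 4,000-5,000 before rounding

    @pytest.mark.parametrize("bad", [-1.0, math.nan, math.inf])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            acc.biomass_movement(bad, 1.0)
        with pytest.raises(InvalidArgumentError):
            acc.biomass_movement(1.0, bad)

    def test_tern_migration_from_population(self):
        assert acc.movement_from_population(2e6, 0.1, 80000) == pytest.approx(1.6e7)

    def test_zero_mass_population(self):
        assert acc.movement_from_population(1e9, 0.0, 5e4) == 0.0

    def test_humpback_scale_matches_land_mammals(self):
        m = acc.movement_from_population(8e4, 30000, 15000)
        assert m == pytest.approx(3.6e10)
        assert 1e10 < m < 1e11  # same order as all wild land mammals (~3e10)

    def test_upper_bound_bacteria(self):
        # 200 Gt at 10 um/s around the clock
        ub = acc.upper_bound_movement(2e11, 24.0, 3.6e-5)
        assert ub == pytest.approx(6.3072e10)
        assert 1e10 < ub < 1e11  # order of the printed tens of Gt km/yr

    def test_upper_bound_zero_activity(self):
        assert acc.upper_bound_movement(1e9, 0.0, 5.0) == 0.0

    def test_upper_bound_activity_over_24h(self):
        with pytest.raises(InvalidArgumentError):
            acc.upper_bound_movement(1e9, 25.0, 5.0)


class TestComparisons:
    def test_walking_share(self):
        assert acc.relative_share(600, 4000) == pytest.approx(0.15)

    def test_share_undefined_for_zero_whole(self):
        with pytest.raises(UndefinedValueError):
            acc.relative_share(1, 0)

    def test_equal_parts_equal_shares(self):
        assert acc.composition_shares([3, 3, 3]) == pytest.approx([100 / 3] * 3)

    def test_marine_composition(self):
        shares = acc.composition_shares([21000, 4500, 3000, 1500])
        assert shares == pytest.approx([70, 15, 10, 5])

    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=12))
    def test_shares_sum_to_100(self, parts):
        assert math.fsum(acc.composition_shares(parts)) == pytest.approx(100.0, abs=1e-9)

    def test_marine_decline(self):
        d = acc.decline_percent(80000, 30000)
        assert d == pytest.approx(62.5)
        assert round(d, -1) == 60  # prints as ~60%

    def test_no_change_no_decline(self):
        assert acc.decline_percent(123.0, 123.0) == 0.0

    @given(st.floats(min_value=0.1, max_value=1e6), st.floats(min_value=0.1, max_value=1e6))
    def test_fold_change_inverse(self, a, b):
        assert acc.fold_change(a, b) * acc.fold_change(b, a) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x,n,expected",
        [(75, 1, 80), (33333, 1, 30000), (4.1, 1, 4), (0, 3, 0), (-75, 1, -80),
         (0.717, 1, 0.7), (2.85, 1, 3), (96, 1, 100), (1.25, 2, 1.3)],
    )
    def test_round_sigfig(self, x, n, expected):
        assert acc.round_sigfig(x, n) == pytest.approx(expected)

    def test_round_sigfig_invalid_n(self):
        with pytest.raises(InvalidArgumentError):
            acc.round_sigfig(1.0, 0)


class TestSpeciesRecord:
    def test_requires_some_distance_information(self):
        with pytest.raises(InvalidArgumentError):
            SpeciesRecord(id="x", group_path=("a",), locomotion_mode="walk_run",
                          biomass_t=UncertainValue.exact(1.0))

    def test_population_mass_consistency_check(self):
        with pytest.raises(InvalidArgumentError, match="disagrees"):
            SpeciesRecord(id="x", group_path=("a",), locomotion_mode="walk_run",
                          biomass_t=UncertainValue.exact(1000.0),
                          population=1e6, body_mass_kg=10.0,  # implies 10,000 t
                          daily_distance_km=UncertainValue.exact(1.0))

    def test_consistent_population_accepted(self):
        rec = SpeciesRecord(id="x", group_path=("a",), locomotion_mode="walk_run",
                            biomass_t=UncertainValue.exact(10000.0),
                            population=1e6, body_mass_kg=10.0,
                            daily_distance_km=UncertainValue.exact(1.0))
        assert rec.resolve_annual_distance().mean == pytest.approx(365.0)


class TestAggregation:
    def test_three_leaf_additivity(self):
        root = GroupNode("total", [leaf(i, 1e9, annual_km=10.0) for i in range(3)])
        res = acc.aggregate(root)
        assert res.root.estimate.movement_t_km_yr.mean == pytest.approx(3e10)

    def test_terrestrial_groups_sum_to_100_gt(self):
        # mammals ~30 + arthropods ~30 + birds ~40 -> ~100 Gt km/yr
        mammals = GroupNode("mammals", [leaf(0, 2e7, daily_km=4.1)])
        arthropods = GroupNode("arthropods", [leaf(1, 1e9, daily_km=0.082)])
        birds = GroupNode("birds", [leaf(2, 3e6, daily_km=36.5)])
        root = GroupNode("land", [mammals, arthropods, birds])
        total = acc.aggregate(root).root.estimate.movement_t_km_yr.mean / GT
        assert acc.round_sigfig(total, 1) == 100

    def test_matches_brute_force_flat_sum(self, rng):
        leaves = [leaf(i, float(rng.lognormal(10, 2)), daily_km=float(rng.lognormal(0, 1)))
                  for i in range(200)]
        # arbitrary nesting: chunks of unequal size
        tree = GroupNode("root", [
            GroupNode("a", leaves[:37]),
            GroupNode("b", [GroupNode("b1", leaves[37:120]), GroupNode("b2", leaves[120:150])]),
            *leaves[150:],
        ])
        expected = math.fsum(
            l.biomass_t.mean * l.daily_distance_km.mean * UNITS.days_per_year for l in leaves
        )
        got = acc.aggregate(tree).root.estimate.movement_t_km_yr.mean
        assert got == pytest.approx(expected, rel=1e-9)

    def test_permutation_invariance(self, rng):
        leaves = [leaf(i, float(rng.lognormal(8, 1)), daily_km=float(rng.lognormal(0, 1)))
                  for i in range(20)]
        a = acc.aggregate(GroupNode("r", list(leaves))).root.estimate
        perm = [leaves[i] for i in rng.permutation(20)]
        b = acc.aggregate(GroupNode("r", perm)).root.estimate
        assert a.movement_t_km_yr.mean == pytest.approx(b.movement_t_km_yr.mean, rel=1e-12)

    def test_scale_equivariance(self, rng):
        leaves = [leaf(i, float(rng.lognormal(8, 1)), daily_km=float(rng.lognormal(0, 1)))
                  for i in range(15)]
        base = acc.aggregate(GroupNode("r", list(leaves))).root.estimate
        k = 7.5
        scaled_leaves = [
            leaf(i, l.biomass_t.mean * k, daily_km=l.daily_distance_km.mean)
            for i, l in enumerate(leaves)
        ]
        scaled = acc.aggregate(GroupNode("r", scaled_leaves)).root.estimate
        assert scaled.movement_t_km_yr.mean == pytest.approx(
            base.movement_t_km_yr.mean * k, rel=1e-12)

    def test_bound_only_leaf_excluded_from_mean(self):
        known = leaf(0, 1e9, annual_km=100.0)
        bound_only = leaf(1, 1e9, activity=12.0, speed=1.0)
        res = acc.aggregate(GroupNode("r", [known, bound_only]))
        est = res.root.estimate
        assert est.movement_t_km_yr.mean == pytest.approx(1e11)  # only the known leaf
        assert est.upper_bound_t_km_yr == pytest.approx(1e11 + 1e9 * 12 * 365)
        assert res.coverage.n_bound_only == 1
        assert res.coverage.n_estimated == 1

    def test_upper_bound_dominates_mean_when_activity_given(self):
        # an activity x speed bound chosen above the daily range
        l = leaf(0, 1e8, daily_km=4.0, activity=12.0, speed=2.0)
        est = acc.aggregate(GroupNode("r", [l])).root.estimate
        assert est.upper_bound_t_km_yr >= est.movement_t_km_yr.mean

    def test_weighted_distance_brute_force(self, rng):
        bundle = gen_species_table(11)
        res = acc.aggregate(bundle.data["tree"])
        est = res.root.estimate
        table = bundle.data["table"]
        expected = np.average(table["daily_distance_km_mean"], weights=table["biomass_t_mean"])
        got = acc.weighted_mean_daily_distance(est)
        assert got == pytest.approx(expected, rel=1e-9)
        assert table["daily_distance_km_mean"].min() <= got <= table["daily_distance_km_mean"].max()

    def test_weighted_distance_headline(self):
        est = acc.MovementEstimate(
            movement_t_km_yr=UncertainValue.exact(3e10),
            biomass_t=UncertainValue.exact(2e7),
        )
        d = acc.weighted_mean_daily_distance(est)
        assert d == pytest.approx(4.11, abs=0.01)
        assert acc.round_sigfig(d, 1) == 4

    def test_weighted_distance_zero_biomass(self):
        est = acc.MovementEstimate(
            movement_t_km_yr=UncertainValue.exact(1.0),
            biomass_t=UncertainValue.exact(0.0),
        )
        with pytest.raises(UndefinedValueError):
            acc.weighted_mean_daily_distance(est)


class TestCsvRoundTrip:
    def test_species_csv_roundtrip_preserves_aggregate(self, tmp_path):
        bundle = gen_species_table(5, SpeciesTableConfig())
        path = tmp_path / "species.csv"
        bundle.data["table"].to_csv(path, index=False)
        root = acc.read_species_csv(path)
        res = acc.aggregate(root)
        assert res.root.estimate.movement_t_km_yr.mean == pytest.approx(
            bundle.truth["total_movement_t_km_yr"], rel=1e-9)
        assert res.coverage.n_leaves == len(bundle.data["table"])
        assert res.coverage.n_skipped == 0
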