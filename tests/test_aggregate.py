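"""Species, basin, subbasin, and trait-group aggregation of CI values."""

import numpy as np
import pandas as pd
import pytest

from rangeconnect import (
    SchemaError,
    SpeciesRange,
    basin_mean_ci,
    compare_dam_sets,
    compute_ci_table,
    delta_ci,
    group_mean_ci,
    species_mean_ci,
    subbasin_mean_ci,
)

from conftest import small_world


def ci_rows(*rows):
    return pd.DataFrame(
        rows,
        columns=["species_id", "main_basin_id", "scenario", "diadromy",
                 "ci_percent", "range_area_km2"],
    )


class TestSpeciesMean:
    def test_single_basin_identity(self):
        t = ci_rows(("s", "b0", "present", "nondiadromous", 73.5, 42.0))
        out = species_mean_ci(t)
        assert out.ci_percent.tolist() == [73.5]

    def test_hand_computed_weighted_mean(self):
        t = ci_rows(("s", "b0", "present", "nondiadromous", 40.0, 100.0),
                    ("s", "b1", "present", "nondiadromous", 80.0, 300.0))
        assert species_mean_ci(t).ci_percent.iloc[0] == pytest.approx(70.0)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(8)
        ci = rng.uniform(0, 100, 5)
        w = rng.uniform(1, 50, 5)
        t = ci_rows(*[("s", f"b{i}", "present", "nondiadromous", ci[i], w[i])
                      for i in range(5)])
        got = species_mean_ci(t).ci_percent.iloc[0]
        assert got == pytest.approx(float(ci @ w / w.sum()), rel=1e-12)
        assert min(ci) <= got <= max(ci)

    def test_equal_weights_reduce_to_plain_mean(self):
        t = ci_rows(("s", "b0", "present", "nondiadromous", 20.0, 7.0),
                    ("s", "b1", "present", "nondiadromous", 90.0, 7.0))
        assert species_mean_ci(t).ci_percent.iloc[0] == pytest.approx(55.0)

    def test_zero_weight_rejected(self):
        t = ci_rows(("s", "b0", "present", "nondiadromous", 50.0, 0.0))
        with pytest.raises(SchemaError):
            species_mean_ci(t)

    def test_total_range_area_is_summed(self):
        t = ci_rows(("s", "b0", "present", "nondiadromous", 40.0, 100.0),
                    ("s", "b1", "present", "nondiadromous", 80.0, 300.0))
        assert species_mean_ci(t).range_area_km2.iloc[0] == pytest.approx(400.0)


class TestBasinAndSubbasinMean:
    def test_basin_mean_is_unweighted(self):
        t = ci_rows(("s1", "b0", "present", "nondiadromous", 60.0, 1.0),
                    ("s2", "b0", "present", "nondiadromous", 80.0, 99.0))
        out = basin_mean_ci(t)
        assert out.mean_ci.iloc[0] == pytest.approx(70.0)
        assert out.n_species.iloc[0] == 2

    def test_subbasin_mean_two_species(self):
        from conftest import chain_network
        net = chain_network([1.0, 1.0])
        t = ci_rows(("s1", "b0", "present", "nondiadromous", 60.0, 1.0),
                    ("s2", "b0", "present", "nondiadromous", 80.0, 2.0))
        ranges = [SpeciesRange("s1", frozenset({"u0", "u1"}), "nondiadromous"),
                  SpeciesRange("s2", frozenset({"u1"}), "nondiadromous")]
        out = subbasin_mean_ci(t, ranges, "present", net)
        assert out["u0"] == pytest.approx(60.0)   # one species
        assert out["u1"] == pytest.approx(70.0)   # mean of 60, 80
        assert "u2" not in out.index

    def test_subbasin_mean_matches_per_unit_oracle(self, world):
        t = compute_ci_table(world.network, world.dams, world.ranges, "present")
        out = subbasin_mean_ci(t, world.ranges, "present", world.network)
        lookup = {(r.species_id, r.main_basin_id): r.ci_percent
                  for r in t.itertuples(index=False)}
        rng = np.random.default_rng(3)
        units = rng.choice(out.index, size=15, replace=False)
        for u in units:
            vals = [
                lookup[(r.species, world.network.units[u].main_basin)]
                for r in world.ranges if u in r.units
            ]
            assert out[u] == pytest.approx(float(np.mean(vals)), rel=1e-12)


def species_table(n_by_order, scenario="present"):
    rows, k = [], 0
    for order, n in n_by_order.items():
        for _ in range(n):
            rows.append({"species_id": f"s{k:03d}", "scenario": scenario,
                         "diadromy": "nondiadromous",
                         "ci_percent": 50.0 + (k % 40),
                         "range_area_km2": 10.0 ** (1 + k % 5)})
            k += 1
    sp = pd.DataFrame(rows)
    meta = pd.DataFrame({
        "species_id": sp.species_id,
        "order": [o for o, n in n_by_order.items() for _ in range(n)],
    }).set_index("species_id")
    return sp, meta


class TestGroupMean:
    def test_small_orders_merge_into_other(self):
        sp, meta = species_table({"Cypriniformes": 25, "Osmeriformes": 5})
        out = group_mean_ci(sp, meta, "order")
        counts = dict(zip(out.category, out.n_species))
        assert counts == {"Cypriniformes": 25, "other": 5}

    def test_groups_partition_species_with_trait(self):
        sp, meta = species_table({"A" * 3: 22, "B" * 3: 30, "Ccc": 7, "Ddd": 4})
        meta.iloc[:5, 0] = pd.NA  # first five lose their trait
        out = group_mean_ci(sp, meta, "order")
        assert out.n_species.sum() == len(sp) - 5

    def test_all_missing_trait_gives_empty_summary(self):
        sp, meta = species_table({"X": 10})
        meta["order"] = pd.NA
        out = group_mean_ci(sp, meta, "order")
        assert out.empty

    def test_order_statistics_consistent(self):
        sp, meta = species_table({"Cypriniformes": 40})
        row = group_mean_ci(sp, meta, "order").iloc[0]
        assert row["p2_5"] <= row["q25"] <= row["median"] <= row["q75"] <= row["p97_5"]
        ci = sp.ci_percent.to_numpy()
        assert row["mean"] == pytest.approx(ci.mean())
        assert row["sd"] == pytest.approx(ci.std(ddof=1))
        assert row["median"] == pytest.approx(np.percentile(ci, 50))

    def test_log10_range_area_binning_matches_oracle(self):
        sp, meta = species_table({"Cypriniformes": 50})
        out = group_mean_ci(sp, meta, "range_area_km2")
        # oracle: brute-force histogram on log10 areas over the same edges
        logs = np.log10(sp.range_area_km2.to_numpy())
        lo, hi = int(np.floor(logs.min())), int(np.ceil(logs.max()))
        edges = list(range(lo + 1, hi))
        counts = dict(zip(out.category, out.n_species))
        brute = np.histogram(logs, bins=[-np.inf, *edges, np.inf])[0]
        assert sorted(counts.values(), reverse=True) == sorted(
            [int(c) for c in brute if c], reverse=True)
        assert out.n_species.sum() == len(sp)

    def test_length_binning_first_bin_is_under_5(self):
        sp, meta = species_table({"Cypriniformes": 30})
        meta["max_length_cm"] = [3.0] * 10 + [12.0] * 10 + [100.0] * 10
        out = group_mean_ci(sp, meta, "max_length_cm")
        counts = dict(zip(out.category, out.n_species))
        assert counts == {"<5": 10, "10-20": 10, ">=80": 10}

    def test_unknown_grouping_rejected(self):
        sp, meta = species_table({"X": 25})
        with pytest.raises(SchemaError, match="grouping"):
            group_mean_ci(sp, meta, "wingspan")


class TestDeltaAndComparison:
    def test_identical_tables_zero_delta(self):
        t = ci_rows(("s", "b0", "present", "nondiadromous", 50.0, 1.0))
        f = t.assign(scenario="future")
        assert (delta_ci(t, f).delta == 0.0).all()

    def test_eighty_one_to_seventy_one_drops_ten(self):
        p = ci_rows(("s", "b0", "present", "nondiadromous", 81.0, 1.0))
        f = ci_rows(("s", "b0", "future", "nondiadromous", 71.0, 1.0))
        assert delta_ci(p, f).delta.iloc[0] == pytest.approx(10.0)

    def test_key_mismatch_rejected(self):
        p = ci_rows(("s1", "b0", "present", "nondiadromous", 50.0, 1.0))
        f = ci_rows(("s2", "b0", "future", "nondiadromous", 50.0, 1.0))
        with pytest.raises(SchemaError, match="mismatch"):
            delta_ci(p, f)

    def test_monotone_pair_all_deltas_nonnegative(self, world):
        p = compute_ci_table(world.network, world.dams, world.ranges, "present")
        f = compute_ci_table(world.network, world.dams, world.ranges, "future")
        assert (delta_ci(p, f).delta >= -1e-12).all()

    def test_same_dam_set_zero_mean_difference(self):
        ds = small_world(seed=17)
        cmp = compare_dam_sets(ds.network, ds.ranges, ds.dams, ds.dams)
        assert cmp.mean_delta == 0.0
        assert (cmp.per_species.delta == 0.0).all()

    def test_extra_dams_produce_positive_mean_drop(self):
        ds = small_world(seed=18, n_dams_existing=5, n_dams_future=0)
        from rangeconnect.simulate import SynthConfig, generate_dams
        bigger = generate_dams(
            ds.network,
            SynthConfig(seed=99, n_units=120, n_basins=4,
                        n_dams_existing=40, n_dams_future=0))
        both = pd.concat([ds.dams, bigger], ignore_index=True)
        both["dam_id"] = [f"d{i}" for i in range(len(both))]
        both = both.drop_duplicates("unit_id")
        cmp = compare_dam_sets(ds.network, ds.ranges, ds.dams, both)
        assert cmp.mean_delta > 0.0
        assert (cmp.per_species.delta >= -1e-12).all()
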