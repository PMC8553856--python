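"""Environment model, sharing classes, distance/interval indices, schedules."""

import math

import numpy as np
import pandas as pd
import pytest

from overlapmaps.design import (
    CENTER,
    LOCALIZER_STORES,
    TRIAL_DURATION_S,
    Triad,
    build_environment,
    enumerate_spatial_triads,
    generate_localizer_schedule,
    generate_retrieval_schedule,
    read_events_tsv,
    spatial_distance_index,
    temporal_interval_index,
    triad_equality,
    write_events_tsv,
)


class TestEnvironment:
    def test_city_pair_overlaps(self, env):
        assert len(env.overlap(1, 2)) == 5
        assert len(env.overlap(2, 3)) == 4
        assert len(env.overlap(1, 3)) == 3
        assert env.cities[1] & env.cities[2] & env.cities[3] == {1, 3, 5}

    def test_self_intersection_identity(self, env):
        for c in (1, 2, 3):
            assert len(env.overlap(c, c)) == 6

    def test_duration_assignment(self, env):
        assert {s for s, d in env.durations.items() if d == 8} == {3, 5, 6, 9}
        assert {s for s, d in env.durations.items() if d == 16} == {1, 2, 4, 7, 8}

    def test_shared_slot_across_cities(self, env):
        # a store keeps its physical slot in every city containing it
        for s in (1, 3, 5, 2, 6, 7):
            coords = env.coords(s)
            assert np.linalg.norm(coords) == pytest.approx(env.radius)
        assert env.slot_of(CENTER) is None
        assert np.allclose(env.coords(CENTER), 0.0)

    @pytest.mark.parametrize(
        "bad",
        [
            {"cities": {1: [1, 2, 3, 4, 5], 2: [1, 2, 3, 5, 6, 7], 3: [1, 3, 5, 7, 8, 9]}},
            {"cities": {1: [1, 2, 3, 4, 5, 8], 2: [1, 2, 3, 5, 6, 7], 3: [1, 3, 5, 7, 8, 9]}},
        ],
    )
    def test_invalid_city_definitions_rejected(self, bad):
        # wrong store count, or two stores mapped to one slot within a city
        with pytest.raises(ValueError):
            build_environment(bad)

    def test_unknown_store_rejected(self, env):
        with pytest.raises(KeyError):
            env.cities_containing(77)


class TestSharingClass:
    @pytest.mark.parametrize(
        "stores,level,cities",
        [
            ((1, 4, 5), "unique", {1}),
            ((2, 1, 6), "two_shared", {1, 2}),
            ((1, 3, 5), "three_shared", {1, 2, 3}),
            ((3, 8, 9), "unique", {3}),
            ((7, 3, 5), "two_shared", {2, 3}),
        ],
    )
    def test_triad_classification(self, env, stores, level, cities):
        sc = env.classify_sharing(stores)
        assert sc.level == level
        assert sc.attributable_cities == cities

    def test_store_partition(self, env):
        by_level = {"unique": set(), "two_shared": set(), "three_shared": set()}
        for s in sorted(env.all_stores - {CENTER}):
            by_level[env.classify_sharing(s).level].add(s)
        assert by_level == {
            "unique": {4, 8, 9},
            "two_shared": {2, 6, 7},
            "three_shared": {1, 3, 5},
        }

    def test_center_never_restricts_attribution(self, env):
        assert env.classify_sharing((CENTER, 3, 5)).attributable_cities == {1, 2, 3}


class TestDistanceIndices:
    def test_bottom_swap_invariance(self, env):
        for t in enumerate_spatial_triads(env, 1):
            swapped = Triad(t.top, t.bottom_right, t.bottom_left, "spatial", t.city)
            assert spatial_distance_index(t, env) == pytest.approx(
                spatial_distance_index(swapped, env)
            )

    def test_mirror_symmetric_bottoms_are_equal(self, env):
        # stores 2 and 6 flank store 1 symmetrically on the hexagon
        t = Triad(1, 2, 6, "spatial", 1)
        assert triad_equality(t, env) == "equal"

    def test_degenerate_zero_radius_layout(self):
        env0 = build_environment({"radius": 0.0})
        t = Triad(1, 2, 6, "spatial", 1)
        assert spatial_distance_index(t, env0) == 0.0

    def test_distinct_distance_values_match_enumeration_oracle(self, env):
        # independent oracle: chord between slots k apart is 2 R sin(pi k / 6);
        # top-to-bottom legs can be 1, sqrt(3) or 2 (antipode), and only one
        # store sits at the antipode, so the sums {1,1},{1,s3},{1,2},{s3,s3},
        # {s3,2} are realizable but {2,2} is not -> 5 distinct index values.
        chord = lambda k: 2.0 * env.radius * math.sin(math.pi * k / 6.0)
        legs = [chord(1), chord(2), chord(3)]
        oracle = set()
        for city in (1, 2, 3):
            slots = {env.slot_of(s) for s in env.cities[city]}
            for top in slots:
                others = [s for s in slots if s != top]
                for i in range(len(others)):
                    for j in range(i + 1, len(others)):
                        d1 = legs[min(abs(top - others[i]), 6 - abs(top - others[i])) - 1]
                        d2 = legs[min(abs(top - others[j]), 6 - abs(top - others[j])) - 1]
                        oracle.add(round(d1 + d2, 9))
        observed = {
            round(spatial_distance_index(t, env), 9)
            for city in (1, 2, 3)
            for t in enumerate_spatial_triads(env, city)
        }
        assert observed == oracle
        assert len(observed) == 5

    def test_spatial_index_rejects_temporal_triad(self, env):
        t = Triad(CENTER, 3, 5, "temporal", 1)
        with pytest.raises(ValueError):
            spatial_distance_index(t, env)


class TestTemporalIndex:
    @pytest.mark.parametrize("bl,br,expected", [(1, 2, 32), (3, 5, 16), (3, 1, 24)])
    def test_printed_examples(self, env, bl, br, expected):
        t = Triad(CENTER, bl, br, "temporal", 1)
        assert temporal_interval_index(t, env) == expected

    def test_only_three_values_possible(self, env):
        vals = {
            temporal_interval_index(Triad(CENTER, a, b, "temporal", c), env)
            for c in (1, 2, 3)
            for a in env.cities[c]
            for b in env.cities[c]
            if a < b
        }
        assert vals == {16, 24, 32}

    def test_non_center_top_rejected(self, env):
        with pytest.raises(ValueError):
            Triad(1, 3, 5, "temporal", 1)


class TestRetrievalSchedule:
    def test_totals_and_ratios(self, schedule):
        assert len(schedule) == 180
        assert (schedule.groupby("run").size() == 15).all()
        assert (schedule["equality"] == "unequal").sum() == 108
        assert (schedule["equality"] == "equal").sum() == 72
        for task in ("spatial", "temporal"):
            sub = schedule[schedule["task"] == task]
            assert len(sub) == 90
            assert (sub["equality"] == "unequal").mean() == pytest.approx(0.6)

    def test_run_structure(self, schedule):
        runs = schedule.drop_duplicates("run").sort_values("run")
        assert list(runs["task"])[:6] == [list(runs["task"])[0]] * 6  # consecutive blocks
        per = runs.groupby(["task", "city"]).size()
        assert (per == 2).all()

    def test_trial_timing(self, schedule):
        run1 = schedule[schedule["run"] == 1]
        onsets = run1["onset"].to_numpy()
        assert np.allclose(np.diff(onsets), TRIAL_DURATION_S)
        assert (run1["duration"] == 9.0).all()

    def test_determinism(self, env, schedule):
        again = generate_retrieval_schedule(env, rng_seed=11)
        pd.testing.assert_frame_equal(schedule, again)

    @pytest.mark.parametrize("block", range(10))
    def test_city_order_constraints_many_seeds(self, env, block):
        # 100 seeds per parametrized block: no city twice in a row, every city
        # visited before any repeat, per-run quotas hold
        for seed in range(block * 100, block * 100 + 100):
            sched = generate_retrieval_schedule(env, seed)
            runs = sched.drop_duplicates("run").sort_values("run")
            for task in ("spatial", "temporal"):
                cities = list(runs.loc[runs["task"] == task, "city"])
                assert len(cities) == 6
                assert all(a != b for a, b in zip(cities, cities[1:]))
                assert set(cities[:3]) == {1, 2, 3} and set(cities[3:]) == {1, 2, 3}
            eq = sched.groupby("run")["equality"].apply(lambda s: (s == "equal").sum())
            assert (eq == 6).all()

    def test_cross_city_anchor_coverage(self, schedule):
        # every spatial run carries the tri-city {1,3,5} probe so the
        # three-shared between-city condition always has pairs
        spatial = schedule[schedule["task"] == "spatial"]
        for run, grp in spatial.groupby("run"):
            sets = [
                frozenset(r) for r in grp[["store_top", "store_bl", "store_br"]].to_numpy()
            ]
            assert frozenset({1, 3, 5}) in sets


class TestLocalizerSchedule:
    def test_counts(self, localizer):
        assert len(localizer) == 36
        assert (localizer.groupby("run").size() == 18).all()
        assert localizer.groupby("old_store").size().eq(6).all()

    def test_positions_balanced_within_run(self, localizer):
        for (_, s), grp in localizer.groupby(["run", "old_store"]):
            assert sorted(grp["position"]) == ["bl", "br", "top"]

    def test_repetition_spacing(self, localizer):
        for run, grp in localizer.groupby("run"):
            order = grp.reset_index(drop=True)
            for s in LOCALIZER_STORES:
                idx = order.index[order["old_store"] == s].to_numpy()
                gaps = np.diff(idx)
                assert ((gaps >= 2) & (gaps <= 12)).all()

    def test_fillers_are_unstudied(self, localizer):
        for _, row in localizer.iterrows():
            shown = {row["store_top"], row["store_bl"], row["store_br"]}
            assert row["old_store"] in shown
            assert all(s >= 100 for s in shown - {row["old_store"]})


def test_events_tsv_round_trip(tmp_path, schedule):
    p = tmp_path / "events.tsv"
    write_events_tsv(schedule, p)
    back = read_events_tsv(p)
    assert len(back) == len(schedule)
    assert (back["store_top"] == schedule["store_top"]).all()
    assert back["onset"].to_numpy() == pytest.approx(schedule["onset"].to_numpy())


def test_environment_json_round_trip(tmp_path, env):
    p = tmp_path / "env.json"
    env.to_json(p)
    back = type(env).from_json(p)
    assert back.cities == dict(env.cities)
    assert back.slots == dict(env.slots)
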