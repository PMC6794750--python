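"""Orientation, conflict resolution and consensus-map construction."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from metaqtl_forge.consensus import (build_consensus, build_consensus_group,
                                     detect_order_conflicts,
                                     drop_unlinked_groups,
                                     map_order_correlation, orient_groups,
                                     resolve_inversions)
from metaqtl_forge.models import ConsensusMap, GeneticMap, Marker
from metaqtl_forge.simulate import SimulationConfig, simulate_all


def make_map(map_id, names_positions, lg="1"):
    return GeneticMap(map_id, groups={
        lg: [Marker(n, lg, p) for n, p in names_positions]})


def consensus_as_map(cmap: ConsensusMap, map_id="cons") -> GeneticMap:
    return GeneticMap(map_id, groups={
        lg: [Marker(m.name, lg, m.pos_cm) for m in cmap.markers(lg)]
        for lg in cmap.lgs})


class TestOrientation:
    def test_reversed_group_is_flipped(self):
        ref = make_map("ref", [("A", 0), ("B", 5), ("C", 10)])
        comp = make_map("c", [("C", 0), ("B", 5), ("A", 10)])
        out, unori = orient_groups(comp, ref)
        assert not unori
        assert out.positions("1") == {"A": 0.0, "B": 5.0, "C": 10.0}

    def test_identical_order_unchanged(self):
        ref = make_map("ref", [("A", 0), ("B", 5), ("C", 10)])
        comp = make_map("c", [("A", 0), ("B", 3), ("C", 20)])
        out, _ = orient_groups(comp, ref)
        assert out.positions("1") == comp.positions("1")

    def test_single_shared_marker_flagged_unorientable(self):
        ref = make_map("ref", [("A", 0), ("Z", 9)])
        comp = make_map("c", [("A", 0), ("B", 5)])
        _, unori = orient_groups(comp, ref)
        assert unori == ["1"]

    def test_chosen_orientation_maximizes_rho(self):
        """Against the exhaustive two-option oracle on random maps."""
        rng = np.random.default_rng(7)
        names = [f"m{i}" for i in range(12)]
        for trial in range(30):
            ref = make_map("ref", list(zip(names, np.sort(rng.uniform(0, 100, 12)))))
            perm = rng.permutation(12)
            comp_pos = np.sort(rng.uniform(0, 80, 12))
            comp = make_map("c", [(names[perm[i]], comp_pos[i])
                                  for i in range(12)])
            out, _ = orient_groups(comp, ref)

            def rho(gmap):
                shared = sorted(set(gmap.positions("1")) & set(ref.positions("1")))
                return stats.spearmanr(
                    [gmap.positions("1")[n] for n in shared],
                    [ref.positions("1")[n] for n in shared]).statistic

            top = max(p for p in comp.positions("1").values())
            flipped = make_map("c", [(n, top - p)
                                     for n, p in comp.positions("1").items()])
            assert rho(out) == pytest.approx(max(rho(comp), rho(flipped)))


class TestUnlinkedGroups:
    def test_one_shared_marker_group_removed_two_retained(self):
        a = make_map("a", [("A", 0), ("B", 5), ("C", 9)])
        one = make_map("b", [("A", 0), ("X", 4)])       # shares only A
        two = make_map("c", [("A", 0), ("B", 2), ("Y", 7)])  # shares A, B
        out, removed = drop_unlinked_groups([a, one, two])
        assert ("b", "1") in removed
        assert out[2].n_markers("1") == 3

    def test_planted_isolated_groups_all_removed(self):
        maps = [make_map(f"m{i}", [("A", 0), ("B", 5), (f"u{i}", 9)])
                for i in range(3)]
        k = 2
        for i in range(k):
            maps[i].groups[f"iso{i}"] = [Marker(f"only{i}", f"iso{i}", 0.0),
                                         Marker(f"solo{i}", f"iso{i}", 3.0)]
        out, removed = drop_unlinked_groups(maps)
        assert len(removed) == k
        assert all(lg.startswith("iso") for _, lg in removed)


class TestOrderConflicts:
    def test_abc_vs_acb_yields_single_conflict(self):
        m1 = make_map("m1", [("A", 0), ("B", 1), ("C", 2)])
        m2 = make_map("m2", [("A", 0), ("C", 1), ("B", 2)])
        conflicts = detect_order_conflicts([m1, m2], "1")
        assert [(c.marker_1, c.marker_2) for c in conflicts] == [("B", "C")]

    def test_identical_maps_conflict_free(self):
        m = make_map("m1", [("A", 0), ("B", 1), ("C", 2)])
        m2 = make_map("m2", [("A", 0), ("B", 1), ("C", 2)])
        assert detect_order_conflicts([m, m2], "1") == []

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        names = [f"m{i}" for i in range(10)]
        maps = []
        for j in range(4):
            chosen = sorted(rng.choice(10, 7, replace=False))
            pos = np.sort(rng.uniform(0, 50, 7))
            order = rng.permutation(7)
            maps.append(make_map(
                f"m{j}", [(names[chosen[order[i]]], pos[i]) for i in range(7)]))
        got = {(c.map_a, c.map_b, c.marker_1, c.marker_2)
               for c in detect_order_conflicts(maps, "1")}
        expected = set()
        for a, b in combinations(maps, 2):
            pa, pb = a.positions("1"), b.positions("1")
            for m1, m2 in combinations(sorted(set(pa) & set(pb)), 2):
                if (pa[m1] - pa[m2]) * (pb[m1] - pb[m2]) < 0:
                    expected.add((a.map_id, b.map_id, m1, m2))
        assert got == expected

    def test_resolution_removes_least_represented_marker(self):
        base = [("A", 0), ("B", 5), ("C", 10)]
        maps = [make_map(f"m{i}", base) for i in range(5)]
        # C present only in 2 maps, order inverted vs B in one of them
        maps = maps[:3] + [make_map("m3", [("A", 0), ("B", 5)]),
                           make_map("m4", [("A", 0), ("B", 5)])]
        maps.append(make_map("m5", [("A", 0), ("C", 4), ("B", 8)]))
        out, removed = resolve_inversions(maps, "1")
        assert removed == ["C"]
        assert detect_order_conflicts(out, "1") == []

    def test_no_conflicts_no_removals(self):
        maps = [make_map("a", [("A", 0), ("B", 5)]),
                make_map("b", [("A", 0), ("B", 7)])]
        _, removed = resolve_inversions(maps, "1")
        assert removed == []

    def test_seeded_conflicts_end_conflict_free(self):
        cfg = SimulationConfig(n_planted_inversions=3, jitter_sd_cm=0.0,
                               scale_range=(1.0, 1.0))
        bundle = simulate_all(cfg)
        planted = {tuple(sorted(p[1:])) for p in bundle.truth.inversion_pairs}
        found = set()
        for lg in ("1", "2"):
            found |= {(c.marker_1, c.marker_2)
                      for c in detect_order_conflicts(bundle.maps, lg)}
            cleaned, _ = resolve_inversions(bundle.maps, lg)
            assert detect_order_conflicts(cleaned, lg) == []
        assert found == planted


class TestBuildConsensus:
    def test_identical_maps_give_identity(self):
        base = [("A", 0), ("B", 4), ("C", 11)]
        maps = [make_map(f"m{i}", base) for i in range(5)]
        group = build_consensus_group(maps, "1")
        assert [(m.name, m.pos_cm) for m in group] == \
            [("A", 0.0), ("B", 4.0), ("C", 11.0)]
        assert all(m.n_maps == 5 for m in group)

    def test_unique_marker_calibrated_to_linear_midpoint(self):
        m1 = make_map("m1", [("A", 0), ("B", 5), ("D", 10)])
        m2 = make_map("m2", [("A", 0), ("X", 10), ("D", 20)])
        group = build_consensus_group([m1, m2], "1")
        pos = {m.name: m.pos_cm for m in group}
        assert pos["X"] == pytest.approx(5.0)

    def test_disconnected_map_raises(self):
        m1 = make_map("m1", [("A", 0), ("B", 5), ("C", 9)])
        m2 = make_map("m2", [("X", 0), ("Y", 5)])
        with pytest.raises(ValueError, match="disconnected"):
            build_consensus_group([m1, m2], "1")

    def test_idempotence(self, bundle):
        from metaqtl_forge.consensus import resolve_inversions
        maps = bundle.maps[:6]
        for lg in ("1", "2"):
            maps, _ = resolve_inversions(maps, lg)
        cons = build_consensus(maps, ["1", "2"])
        again = build_consensus([consensus_as_map(cons)], ["1", "2"])
        for lg in ("1", "2"):
            np.testing.assert_allclose(
                [m.pos_cm for m in again.markers(lg)],
                [m.pos_cm for m in cons.markers(lg)], atol=1e-9)
            assert [m.name for m in again.markers(lg)] == \
                [m.name for m in cons.markers(lg)]

    def test_order_recovery_under_default_distortion(self, bundle):
        """Affine-distorted maps: consensus order correlates >= 0.95 with
        the generator's true order on every linkage group."""
        maps = list(bundle.maps)
        for lg in ("1", "2"):
            maps, _ = resolve_inversions(maps, lg)
        cons = build_consensus(maps, ["1", "2"])
        for lg in ("1", "2"):
            true_pos = bundle.truth.true_marker_pos[lg]
            shared = [m for m in cons.markers(lg) if m.name in true_pos]
            assert len(shared) >= 20
            rho = stats.spearmanr([m.pos_cm for m in shared],
                                  [true_pos[m.name] for m in shared]).statistic
            assert rho >= 0.95

    def test_positions_weakly_increasing_and_zero_based(self, bundle):
        maps = list(bundle.maps)
        for lg in ("1", "2"):
            maps, _ = resolve_inversions(maps, lg)
        cons = build_consensus(maps, ["1", "2"])
        for lg in cons.lgs:
            pos = [m.pos_cm for m in cons.markers(lg)]
            assert pos[0] == pytest.approx(0.0)
            assert all(b >= a - 1e-12 for a, b in zip(pos, pos[1:]))
            assert all(m.n_maps >= 1 for m in cons.markers(lg))


class TestOrderCorrelation:
    def test_identical_subset_gives_rho_one(self):
        comp = make_map("c", [("A", 0), ("B", 5), ("C", 9)])
        cons = build_consensus([comp], ["1"])
        res = map_order_correlation(comp, cons)
        assert res["1"][0] == pytest.approx(1.0)
        assert res["overall"][0] == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        comp = make_map("c", [("A", 0), ("B", 5), ("C", 9)])
        rev = make_map("r", [("C", 0), ("B", 5), ("A", 9)])
        cons = build_consensus([comp], ["1"])
        assert map_order_correlation(rev, cons)["1"][0] == pytest.approx(-1.0)

    def test_matches_direct_rank_formula(self):
        rng = np.random.default_rng(11)
        names = [f"m{i}" for i in range(15)]
        comp = make_map("c", list(zip(names, np.sort(rng.uniform(0, 90, 15)))))
        cons_pos = rng.permutation(15).astype(float)
        cons = build_consensus(
            [make_map("x", list(zip(names, cons_pos)))], ["1"])
        rho, n = map_order_correlation(comp, cons)["1"]
        expected = stats.spearmanr(
            [comp.positions("1")[m] for m in names],
            [cons.positions("1")[m] for m in names]).statistic
        assert n == 15 and rho == pytest.approx(expected)

    def test_too_few_shared_markers_undefined(self):
        comp = make_map("c", [("A", 0), ("B", 5)])
        cons = build_consensus([make_map("x", [("A", 0), ("B", 5)])], ["1"])
        assert map_order_correlation(comp, cons)["1"] is None
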