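import numpy as np
import pandas as pd
import pytest

import clamap
from clamap.consensus_builder import sarf, _local_search
from oracles import all_path_orders, brute_force_sarf

PERMS6 = all_path_orders(6)
PERMS8 = all_path_orders(8)


def _maps_from_chrom_assignments(assignments):
    """Build trivial maps from {map_index: {marker: chromosome}}."""
    maps = []
    for chrom_of in assignments:
        counter = {}
        rows = []
        for mk, ch in chrom_of.items():
            counter[ch] = counter.get(ch, 0) + 1.0
            rows.append((mk, ch, counter[ch]))
        rows.sort(key=lambda r: (r[1], r[2]))
        maps.append(
            clamap.GeneticMap(
                pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"])
            )
        )
    return maps


class TestAssignGroups:
    def test_consistent_marker_becomes_anchor(self):
        maps = _maps_from_chrom_assignments(
            [{"a": "2B", "b": "2B", "z": "1A"}, {"a": "2B", "b": "2B"}]
        )
        groups, _ = clamap.assign_groups(maps)
        by_chrom = {g.chromosome: g for g in groups}
        assert by_chrom["2B"].anchors == ["a", "b"]
        assert by_chrom["1A"].markers == ["z"] and by_chrom["1A"].anchors == []

    def test_conflict_without_genotypes_dropped_and_logged(self):
        maps = _maps_from_chrom_assignments(
            [{"a": "7A", "x": "7A"}, {"a": "1A", "x": "7A"}]
        )
        groups, log = clamap.assign_groups(maps)
        all_markers = [m for g in groups for m in g.markers]
        assert "a" not in all_markers
        assert (log["event"] == "dropped_conflict_unresolvable").any()

    def test_conflict_resolved_by_linkage_to_anchors(self):
        # marker "c" sits on chromosome "B" in one map, "A" in another, but
        # its genotypes are tightly linked to the A anchors
        rng = np.random.default_rng(5)
        design = clamap.SimulationDesign(
            chromosome_length_cM=20.0,
            marker_positions_cM=np.array([0.0, 5.0, 10.0, 15.0]),
            heritability=0.5,
            n_lines=150,
        )
        genoA, _ = clamap.simulate_genotypes(design, rng)
        genoB, _ = clamap.simulate_genotypes(design, rng)
        codes = np.concatenate([genoA.codes, genoB.codes], axis=1)
        markers = ["a1", "a2", "a3", "c", "b1", "b2", "b3", "b4"]
        pop1 = clamap.GenotypeMatrix([f"l{i}" for i in range(150)], markers, codes)
        pop2 = clamap.GenotypeMatrix([f"k{i}" for i in range(150)], markers, codes)
        maps = _maps_from_chrom_assignments(
            [
                {"a1": "A", "a2": "A", "a3": "A", "c": "A",
                 "b1": "B", "b2": "B", "b3": "B", "b4": "B"},
                {"a1": "A", "a2": "A", "a3": "A", "c": "B",
                 "b1": "B", "b2": "B", "b3": "B", "b4": "B"},
            ]
        )
        groups, log = clamap.assign_groups(maps, [pop1, pop2])
        by_chrom = {g.chromosome: g for g in groups}
        assert "c" in by_chrom["A"].markers
        assert (log["event"] == "conflict_resolved").any()


class TestOrderMarkersTsp:
    def test_two_markers(self):
        order = clamap.order_markers_tsp(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert sorted(order) == [0, 1]

    def test_linear_map_recovered_exactly(self):
        pos = np.array([0.0, 4.0, 9.0, 15.0, 22.0, 30.0])
        dist = np.abs(pos[:, None] - pos[None, :])
        rng = np.random.default_rng(0)
        perm = rng.permutation(6)
        got = clamap.order_markers_tsp(dist[np.ix_(perm, perm)])
        recovered = [perm[i] for i in got]
        assert recovered in ([0, 1, 2, 3, 4, 5], [5, 4, 3, 2, 1, 0])

    def test_six_marker_sarf_against_brute_force(self):
        # noisy map-like instances: nearly always exactly optimal, and never
        # beyond 5% of the exhaustive minimum
        rng = np.random.default_rng(1)
        exact = 0
        for _ in range(40):
            pos = np.sort(rng.uniform(0, 50, 6))
            noise = rng.normal(0, 1.0, (6, 6))
            dist = np.abs(pos[:, None] - pos[None, :]) + np.abs(noise + noise.T)
            np.fill_diagonal(dist, 0.0)
            order = clamap.order_markers_tsp(dist)
            best = brute_force_sarf(dist, PERMS6)
            got = sarf(order, dist)
            assert got <= 1.05 * best + 1e-12
            exact += got <= best + 1e-9
        assert exact >= 36

    def test_local_search_never_worse_than_seed(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            d = rng.uniform(0.1, 10, (7, 7))
            dist = (d + d.T) / 2
            np.fill_diagonal(dist, 0.0)
            seed_order = list(rng.permutation(7))
            improved = _local_search(list(seed_order), dist)
            assert sarf(improved, dist) <= sarf(seed_order, dist) + 1e-12

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.1, 10, (10, 10))
        dist = (d + d.T) / 2
        np.fill_diagonal(dist, 0.0)
        assert clamap.order_markers_tsp(dist) == clamap.order_markers_tsp(dist.copy())

    def test_single_marker_raises(self):
        with pytest.raises(ValueError):
            clamap.order_markers_tsp(np.zeros((1, 1)))


class TestAssignPositions:
    def _rf(self, markers, r):
        m = len(markers)
        var = np.where(np.isnan(r), np.inf, 1e-4)
        np.fill_diagonal(var, 0.0)
        return clamap.RFMatrix(markers, r, var, np.full((m, m), 100))

    def test_adjacent_haldane_distances(self):
        r = np.array(
            [[0.0, 0.1, np.nan], [0.1, 0.0, 0.1], [np.nan, 0.1, 0.0]]
        )
        rf = self._rf(["a", "b", "c"], r)
        frame, log = clamap.assign_positions(["a", "b", "c"], rf, "haldane")
        np.testing.assert_allclose(
            frame["position_cM"], [0.0, 11.157177, 22.314355], atol=1e-5
        )
        assert not log

    def test_zero_rf_shares_position(self):
        r = np.array([[0.0, 0.0, 0.2], [0.0, 0.0, 0.2], [0.2, 0.2, 0.0]])
        rf = self._rf(["a", "b", "c"], r)
        frame, _ = clamap.assign_positions(["a", "b", "c"], rf, "haldane")
        assert frame["position_cM"].iloc[0] == frame["position_cM"].iloc[1]

    def test_bridge_interpolation_conserves_span(self):
        # a-b not estimable; a-c estimable: b interpolated inside the bridge
        r = np.array(
            [
                [0.0, np.nan, 0.18, 0.3],
                [np.nan, 0.0, 0.1, 0.2],
                [0.18, 0.1, 0.0, 0.1],
                [0.3, 0.2, 0.1, 0.0],
            ]
        )
        rf = self._rf(list("abcd"), r)
        frame, log = clamap.assign_positions(list("abcd"), rf, "haldane")
        span = float(clamap.map_distance(0.18, "haldane"))
        assert frame["position_cM"].iloc[2] == pytest.approx(span)
        assert frame["position_cM"].iloc[1] == pytest.approx(span / 2)
        assert any("bridge" in s for s in log)

    def test_disconnected_group_splits(self):
        r = np.array([[0.0, 0.05, np.nan], [0.05, 0.0, np.nan], [np.nan, np.nan, 0.0]])
        rf = self._rf(["a", "b", "c"], r)
        frame, log = clamap.assign_positions(["a", "b", "c"], rf, "haldane")
        assert frame["segment"].nunique() == 2
        assert any("split" in s for s in log)


class TestPruneInflators:
    def _rf_from_positions(self, pos, bad=None):
        """RF matrix consistent with a linear map; 'bad' marker unlinked."""
        m = len(pos)
        d = np.abs(np.asarray(pos)[:, None] - np.asarray(pos)[None, :])
        r = np.asarray(clamap.inverse_map_distance(d, "haldane"))
        if bad is not None:
            r[bad, :] = r[:, bad] = 0.45
            r[bad, bad] = 0.0
        var = np.full((m, m), 1e-4)
        np.fill_diagonal(var, 0.0)
        return clamap.RFMatrix([f"m{i}" for i in range(m)], r, var, np.full((m, m), 200))

    def test_inflating_marker_removed(self):
        pos = np.arange(0.0, 101.0, 10.0)  # 11 markers, 100 cM
        rf = self._rf_from_positions(pos, bad=5)
        order = [f"m{i}" for i in range(11)]
        pruned, log = clamap.prune_inflators(order, rf, mapping_function="haldane")
        assert "m5" not in pruned
        assert log and log[0][1] == "length_inflation_cM"

    def test_clean_map_untouched(self):
        pos = np.arange(0.0, 101.0, 10.0)
        rf = self._rf_from_positions(pos)
        order = [f"m{i}" for i in range(11)]
        pruned, log = clamap.prune_inflators(order, rf, mapping_function="haldane")
        assert pruned == order and not log


class TestBuildConsensus:
    def test_single_population_recovers_input_order(self):
        truth = clamap.GeneticMap.from_positions(
            [f"m{i:02d}" for i in range(21)], np.linspace(0, 60, 21), chromosome="1A"
        )
        pops, maps = clamap.multi_population_fixture(truth, k=1, overlap=1.0, n=250, seed=4)
        cons = clamap.build_consensus(pops, maps, clamap.ConsensusConfig(mapping_function="haldane"))
        rho = clamap.spearman_collinearity(cons.map.markers, truth.markers)
        assert abs(rho) == pytest.approx(1.0)

    def test_three_population_partial_overlap_recovers_truth(self):
        truth = clamap.GeneticMap.from_positions(
            [f"m{i:02d}" for i in range(51)], np.arange(0.0, 101.0, 2.0), chromosome="3B"
        )
        pops, maps = clamap.multi_population_fixture(
            truth, k=3, overlap=0.5, n=200, seed=11
        )
        cons = clamap.build_consensus(
            pops, maps, clamap.ConsensusConfig(mapping_function="haldane")
        )
        assert set(cons.map.markers) == set(truth.markers)
        rho = clamap.spearman_collinearity(cons.map.markers, truth.markers)
        assert abs(rho) >= 0.99
        # few-to-no pruned markers on clean input
        n_pruned = (cons.pruning_log["reason"] == "length_inflation_cM").sum()
        assert n_pruned <= 1

    def test_variance_reduction_with_identical_populations(self):
        truth = clamap.GeneticMap.from_positions(
            [f"m{i}" for i in range(11)], np.linspace(0, 40, 11)
        )
        pops, maps = clamap.multi_population_fixture(truth, k=3, overlap=1.0, n=150, seed=6)
        markers = truth.markers
        one = clamap.build_rf_matrix(pops[:1], markers)
        three = clamap.build_rf_matrix(pops, markers)
        est = ~np.isnan(one.r) & ~np.isnan(three.r)
        np.fill_diagonal(est, False)
        ratio = one.variance[est] / three.variance[est]
        assert np.median(ratio) == pytest.approx(3.0, rel=0.35)

    def test_disjoint_marker_sets_split(self):
        rng = np.random.default_rng(9)
        design = clamap.SimulationDesign(
            chromosome_length_cM=40.0,
            marker_positions_cM=np.linspace(0, 40, 8),
            heritability=0.5,
            n_lines=100,
        )
        g1, _ = clamap.simulate_genotypes(design, rng)
        g2, _ = clamap.simulate_genotypes(design, rng)
        markers1 = [f"x{i}" for i in range(8)]
        markers2 = [f"y{i}" for i in range(8)]
        pop1 = clamap.GenotypeMatrix(g1.lines, markers1, g1.codes)
        pop2 = clamap.GenotypeMatrix([f"b{i}" for i in range(100)], markers2, g2.codes)
        maps = [
            clamap.GeneticMap.from_positions(markers1, design.marker_positions_cM, "1"),
            clamap.GeneticMap.from_positions(markers2, design.marker_positions_cM, "1"),
        ]
        cons = clamap.build_consensus(pops := [pop1, pop2], maps)
        # no rf bridges the two marker sets: the group must split
        assert len(cons.map.chromosomes) >= 2

    def test_order_invariant_to_input_permutation(self):
        truth = clamap.GeneticMap.from_positions(
            [f"m{i:02d}" for i in range(15)], np.linspace(0, 50, 15)
        )
        pops, maps = clamap.multi_population_fixture(truth, k=2, overlap=1.0, n=200, seed=8)
        cons1 = clamap.build_consensus(pops, maps)
        # permute marker columns of each population
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(15))
        pops2 = [p.subset_markers([p.markers[j] for j in perm]) for p in pops]
        maps2 = maps  # maps unchanged (order information comes from them)
        cons2 = clamap.build_consensus(pops2, maps2)
        assert cons1.map.markers == cons2.map.markers
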