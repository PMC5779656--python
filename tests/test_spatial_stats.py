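"""Network Moran correlogram, critical distance, thinning, SSB."""

import networkx as nx
import numpy as np
import pytest

from ditchsdm.grids import Grid
from ditchsdm.network import DitchGraph, OccurrenceSet, build_graph
from ditchsdm.spatial_stats import (
    MoranProfile,
    critical_distance,
    network_moran_profile,
    spatial_sorting_bias,
    thin_by_distance,
)
from tests.conftest import path_graph_mask


def brute_force_moran(x, W):
    """O(n^2) Moran's I and randomization Z from an explicit weight matrix."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    s0 = W.sum()
    I = (n / s0) * (xc @ W @ xc) / (xc @ xc)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=0) + W.sum(axis=1)) ** 2).sum()
    b2 = n * (xc**4).sum() / ((xc**2).sum()) ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    return I, (I - e_i) / np.sqrt(var)


def ring_weight_matrix(graph: DitchGraph, cells, lo, hi):
    W = np.zeros((len(cells), len(cells)))
    for a in range(len(cells)):
        for b in range(len(cells)):
            if a == b:
                continue
            d = nx.dijkstra_path_length(graph.graph, cells[a], cells[b], weight="length")
            if lo < d <= hi:
                W[a, b] = 1.0
    return W


class TestMoranOracle:
    @pytest.mark.parametrize("n_nodes", [6, 10, 12, 15])
    def test_matches_double_sum_on_path_graphs(self, n_nodes):
        """I and Z equal the explicit O(n^2) double-sum on small path graphs."""
        graph = build_graph(path_graph_mask(n_nodes), outlet=(0, 0))
        cells = sorted(graph.graph.nodes)
        rng = np.random.default_rng(n_nodes)
        x = rng.integers(0, 2, n_nodes).astype(float)
        while len(np.unique(x)) < 2:
            x = rng.integers(0, 2, n_nodes).astype(float)
        lags = np.array([2.0, 6.0, 12.0])
        prof = network_moran_profile(dict(zip(cells, x)), graph, lags=lags)
        edges = [0.0, 2.0, 6.0, 12.0]
        for k in range(len(lags)):
            W = ring_weight_matrix(graph, cells, edges[k], edges[k + 1])
            if W.sum() == 0:
                assert np.isnan(prof.I[k])
                continue
            I, Z = brute_force_moran(x, W)
            assert prof.I[k] == pytest.approx(I, abs=1e-12)
            assert prof.Z[k] == pytest.approx(Z, abs=1e-10)

    def test_matches_double_sum_on_branched_tree(self):
        cells = [(0, j) for j in range(8)] + [(i, 3) for i in range(1, 8)]
        mask = np.zeros((8, 8))
        for r, c in cells:
            mask[r, c] = 1
        graph = build_graph(Grid(mask, cell_size=2.0), outlet=(0, 0))
        cells = sorted(graph.graph.nodes)
        rng = np.random.default_rng(5)
        x = rng.random(len(cells))
        lags = np.array([4.0, 8.0])
        prof = network_moran_profile(dict(zip(cells, x)), graph, lags=lags)
        for k, (lo, hi) in enumerate([(0, 4.0), (4.0, 8.0)]):
            W = ring_weight_matrix(graph, cells, lo, hi)
            I, Z = brute_force_moran(x, W)
            assert prof.I[k] == pytest.approx(I, abs=1e-12)
            assert prof.Z[k] == pytest.approx(Z, abs=1e-10)

    def test_constant_values_rejected(self, path_graph):
        cells = sorted(path_graph.graph.nodes)
        with pytest.raises(ValueError, match="constant"):
            network_moran_profile({c: 1.0 for c in cells}, path_graph)


class TestMoranBehaviour:
    def test_independent_presences_near_null(self, long_path_graph):
        """Random presences: I ~ -1/(n-1) on average and ~95 % of |Z| < 2."""
        cells = sorted(long_path_graph.graph.nodes)
        n = len(cells)
        rng = np.random.default_rng(2)
        rates = []
        mean_I = []
        for _ in range(5):
            x = (rng.random(n) < 0.3).astype(float)
            prof = network_moran_profile(dict(zip(cells, x)), long_path_graph)
            ok = np.isfinite(prof.Z)
            rates.append(np.mean(np.abs(prof.Z[ok]) < 1.96))
            mean_I.append(np.nanmean(prof.I))
        assert np.mean(rates) > 0.85
        assert abs(np.mean(mean_I) - (-1.0 / (n - 1))) < 0.01

    def test_planted_clusters_detected_within_diameter(self, long_path_graph):
        """Randomly placed 20 m presence clusters: strong significance at short
        lags, and a critical distance inside the cluster diameter.

        With half-open lag *rings*, pairs in the ring at the full diameter
        already straddle cluster boundaries, so significance fades slightly
        before 20 m rather than exactly at it.
        """
        cells = sorted(long_path_graph.graph.nodes)
        rng = np.random.default_rng(3)
        x = np.zeros(len(cells))
        pos = 0
        while pos < len(cells) - 20:
            pos += int(rng.integers(15, 60))
            x[pos : pos + 11] = 1.0  # 11 cells = 20 m diameter
        prof = network_moran_profile(dict(zip(cells, x)), long_path_graph)
        assert np.all(prof.Z[prof.lags <= 10.0] > 1.96)
        assert 10.0 <= critical_distance(prof) <= 20.0


class TestCriticalDistance:
    def test_initial_run_rule(self):
        prof = MoranProfile(
            lags=np.array([2.0, 4.0, 6.0, 8.0, 10.0]),
            I=np.zeros(5),
            Z=np.array([3.1, 2.5, 2.0, 1.1, 2.5]),
            n=100,
            pair_counts=np.ones(5, dtype=int),
        )
        assert critical_distance(prof) == 6.0

    def test_no_significance_gives_zero(self):
        prof = MoranProfile(
            lags=np.array([2.0, 4.0]), I=np.zeros(2), Z=np.array([1.0, 3.0]),
            n=50, pair_counts=np.ones(2, dtype=int),
        )
        assert critical_distance(prof) == 0.0

    def test_empty_profile_rejected(self):
        prof = MoranProfile(lags=np.array([]), I=np.array([]), Z=np.array([]),
                            n=10, pair_counts=np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            critical_distance(prof)

    def test_monotone_in_cluster_diameter(self, long_path_graph):
        """Wider planted clusters never shrink the critical distance."""
        cells = sorted(long_path_graph.graph.nodes)
        dists = []
        for width in (5, 10, 20):
            x = np.zeros(len(cells))
            for start in range(0, len(cells) - width, 4 * width):
                x[start : start + width] = 1.0
            prof = network_moran_profile(dict(zip(cells, x)), long_path_graph)
            dists.append(critical_distance(prof))
        assert dists == sorted(dists)


class TestThinning:
    def make_occ(self, graph, presence_every=1):
        cells = sorted(graph.graph.nodes)
        pres = tuple(c for i, c in enumerate(cells) if i % presence_every == 0)
        return OccurrenceSet("sp", presences=pres, absences=tuple(set(cells) - set(pres)))

    def test_zero_distance_identity(self, path_graph):
        occ = self.make_occ(path_graph, presence_every=2)
        assert thin_by_distance(occ, path_graph, 0.0, seed=0) is occ

    def test_pairwise_spacing_postcondition(self):
        graph = build_graph(path_graph_mask(100), outlet=(0, 0))
        occ = OccurrenceSet("sp", presences=tuple(sorted(graph.graph.nodes)), absences=())
        thinned = thin_by_distance(occ, graph, 10.0, seed=1)
        kept = thinned.presences
        for a in kept:
            for b in kept:
                if a != b:
                    d = nx.dijkstra_path_length(graph.graph, a, b, weight="length")
                    assert d >= 10.0
        # on a 198 m line with 10 m spacing: between maximal and maximum packing
        assert 10 <= len(kept) <= 20

    def test_idempotent(self):
        graph = build_graph(path_graph_mask(60), outlet=(0, 0))
        occ = self.make_occ(graph)
        once = thin_by_distance(occ, graph, 8.0, seed=3)
        twice = thin_by_distance(once, graph, 8.0, seed=99)
        assert twice.presences == once.presences
        assert twice.absences == once.absences

    def test_kept_subset_and_classes_independent(self, small_scene):
        cells = small_scene.graph.nodes
        half = len(cells) // 2
        occ = OccurrenceSet("sp", presences=tuple(cells[:half]), absences=tuple(cells[half:]))
        thinned = thin_by_distance(occ, small_scene.graph, 12.0, seed=0)
        assert set(thinned.presences) <= set(occ.presences)
        assert set(thinned.absences) <= set(occ.absences)


class TestSpatialSortingBias:
    def test_symmetric_split_is_unbiased(self):
        graph = build_graph(path_graph_mask(21), outlet=(0, 0))
        train = OccurrenceSet("sp", presences=((0, 10),), absences=())
        test = OccurrenceSet("sp", presences=((0, 6), (0, 14)), absences=((0, 2), (0, 18)))
        diag = spatial_sorting_bias(train, test, graph)
        # presences at 8 m each, absences at 16 m each -> ssb = 8/16
        assert diag.ssb == pytest.approx(0.5)

    def test_equal_distances_give_one(self):
        graph = build_graph(path_graph_mask(21), outlet=(0, 0))
        train = OccurrenceSet("sp", presences=((0, 10),), absences=())
        test = OccurrenceSet("sp", presences=((0, 6),), absences=((0, 14),))
        assert spatial_sorting_bias(train, test, graph).ssb == pytest.approx(1.0)

    def test_adjacent_presences_near_zero(self):
        graph = build_graph(path_graph_mask(40), outlet=(0, 0))
        train = OccurrenceSet("sp", presences=((0, 0),), absences=())
        test = OccurrenceSet("sp", presences=((0, 1),), absences=((0, 39),))
        assert spatial_sorting_bias(train, test, graph).ssb < 0.05

    def test_invariant_to_uniform_edge_rescaling(self):
        coarse = build_graph(path_graph_mask(30, cell_size=2.0), outlet=(0, 0))
        fine = build_graph(path_graph_mask(30, cell_size=6.0), outlet=(0, 0))
        train = OccurrenceSet("sp", presences=((0, 3), (0, 20)), absences=())
        test = OccurrenceSet("sp", presences=((0, 7), (0, 15)), absences=((0, 11), (0, 28)))
        a = spatial_sorting_bias(train, test, coarse).ssb
        b = spatial_sorting_bias(train, test, fine).ssb
        assert a == pytest.approx(b)

    def test_empty_classes_rejected(self):
        graph = build_graph(path_graph_mask(5), outlet=(0, 0))
        empty = OccurrenceSet("sp", presences=(), absences=((0, 1),))
        some = OccurrenceSet("sp", presences=((0, 2),), absences=((0, 3),))
        with pytest.raises(ValueError, match="training"):
            spatial_sorting_bias(empty, some, graph)
        with pytest.raises(ValueError, match="test"):
            spatial_sorting_bias(some, empty, graph)
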