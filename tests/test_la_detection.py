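"""LA demarcation: each stage against an independent oracle, plus
whole-pipeline properties on synthetic tissues."""

import numpy as np
import pandas as pd
import pytest
import shapely

from lymphagg.config import Config
from lymphagg.errors import ValidationError
from lymphagg.io import OUTSIDE, CellMap
from lymphagg.la_detection import (assign_cells_to_las, build_la_polygon,
                                   cluster_seed_cells,
                                   detect_lymphoid_aggregates, merge_clusters,
                                   select_chemokine_seed_cells)
from lymphagg.synthetic import TissueSimParams, generate_tissue

from conftest import random_cellmap


# ---------------------------------------------------------------------------
# independent oracles

def oracle_seeds(cm: CellMap, pair_radius: float, self_pairing: bool = True):
    """O(n^2) scan for CCL19+ cells near a CXCL13+ cell."""
    df = cm.cells
    out = []
    for i, row in df.iterrows():
        if row["CCL19"] < 1:
            continue
        for j, other in df.iterrows():
            if other["CXCL13"] < 1:
                continue
            if i == j and not self_pairing:
                continue
            d = np.hypot(row["x"] - other["x"], row["y"] - other["y"])
            if d <= pair_radius:
                out.append(row["cell_id"])
                break
    return sorted(out)


def oracle_dbscan(xy: np.ndarray, eps: float, min_samples: int) -> list[frozenset]:
    """Reference DBSCAN: dense distance matrix, BFS over core points.

    Returns the set of clusters as frozensets of point indices (border
    points may legitimately attach to either adjacent cluster, so the
    comparison below checks core partitions plus border adjacency).
    """
    n = len(xy)
    d = np.hypot(xy[:, 0, None] - xy[None, :, 0], xy[:, 1, None] - xy[None, :, 1])
    adj = d <= eps
    core = adj.sum(axis=1) >= min_samples  # includes self (d=0)
    labels = np.full(n, -1)
    cluster = 0
    for start in range(n):
        if not core[start] or labels[start] != -1:
            continue
        stack = [start]
        labels[start] = cluster
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if labels[v] == -1:
                    labels[v] = cluster
                    if core[v]:
                        stack.append(v)
        cluster += 1
    return labels, core, adj


# ---------------------------------------------------------------------------
# stage tests

class TestSeedSelection:
    def test_no_cxcl13_means_no_seeds(self):
        df = pd.DataFrame({"cell_id": ["a", "b"], "x": [0.0, 1.0],
                           "y": [0.0, 0.0], "cell_type": ["B", "B"],
                           "CCL19": [1, 1], "CXCL13": [0, 0]})
        cm = CellMap(sample_id="s", cells=df)
        assert select_chemokine_seed_cells(cm) == []

    def test_boundary_at_exactly_pair_radius_is_inclusive(self, tiny_cellmap):
        # c1 is CCL19+ at (0,0); c2 is CXCL13+ at (50,0)
        assert select_chemokine_seed_cells(tiny_cellmap, pair_radius=50.0) == ["c1"]
        assert select_chemokine_seed_cells(tiny_cellmap, pair_radius=49.9) == []

    def test_double_positive_self_pairing_toggle(self):
        df = pd.DataFrame({"cell_id": ["solo"], "x": [0.0], "y": [0.0],
                           "cell_type": ["B"], "CCL19": [2], "CXCL13": [1]})
        cm = CellMap(sample_id="s", cells=df)
        assert select_chemokine_seed_cells(cm, self_pairing=True) == ["solo"]
        assert select_chemokine_seed_cells(cm, self_pairing=False) == []

    def test_missing_chemokine_column_rejected(self):
        df = pd.DataFrame({"cell_id": ["a"], "x": [0.0], "y": [0.0],
                           "cell_type": ["B"], "CCL19": [1]})
        cm = CellMap(sample_id="s", cells=df)
        with pytest.raises(ValidationError, match="CXCL13"):
            select_chemokine_seed_cells(cm)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("self_pairing", [True, False])
    def test_matches_exhaustive_scan_on_random_cells(self, seed, self_pairing):
        cm = random_cellmap(np.random.default_rng(seed), n=200)
        got = select_chemokine_seed_cells(cm, pair_radius=50.0,
                                          self_pairing=self_pairing)
        assert got == oracle_seeds(cm, 50.0, self_pairing)


def _seed_only_cellmap(xy: np.ndarray) -> CellMap:
    n = len(xy)
    df = pd.DataFrame({
        "cell_id": [f"s{i:04d}" for i in range(n)],
        "x": xy[:, 0], "y": xy[:, 1],
        "cell_type": ["B"] * n, "CCL19": 1, "CXCL13": 1,
    })
    return CellMap(sample_id="seeds", cells=df)


class TestSeedClustering:
    def test_fourteen_seeds_below_core_threshold_are_noise(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 10, size=(14, 2))
        cm = _seed_only_cellmap(xy)
        assert cluster_seed_cells(cm, list(cm.cells["cell_id"]),
                                  radius=75, min_cells=15) == []

    def test_fifteen_coincident_seeds_form_one_cluster(self):
        xy = np.full((15, 2), 42.0)
        cm = _seed_only_cellmap(xy)
        clusters = cluster_seed_cells(cm, list(cm.cells["cell_id"]),
                                      radius=75, min_cells=15)
        assert len(clusters) == 1
        assert len(clusters[0].member_ids) == 15
        assert clusters[0].centroid == pytest.approx((42.0, 42.0))

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_dense_matrix_reference(self, seed):
        """Blobs plus scatter, n <= 300: core partition identical to the
        O(n^2) BFS reference; border points attach to an adjacent cluster."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(30, 300))
        centers = rng.uniform(100, 900, size=(3, 2))
        xy = np.vstack([
            centers[rng.integers(0, 3)] + rng.normal(0, 40, size=2)
            if rng.uniform() < 0.8 else rng.uniform(0, 1000, size=2)
            for _ in range(n)])
        eps, min_cells = 75.0, 10
        cm = _seed_only_cellmap(xy)
        clusters = cluster_seed_cells(cm, list(cm.cells["cell_id"]),
                                      radius=eps, min_cells=min_cells)
        ref_labels, core, adj = oracle_dbscan(xy, eps, min_cells)
        ids = cm.cells["cell_id"].to_numpy()
        got = np.full(len(xy), -1)
        for k, cl in enumerate(clusters):
            idx = np.flatnonzero(np.isin(ids, cl.member_ids))
            got[idx] = k
        # noise sets identical
        np.testing.assert_array_equal(got == -1, ref_labels == -1)
        # core points: identical partition (up to label names)
        for lab in set(ref_labels[core]):
            members = np.flatnonzero(core & (ref_labels == lab))
            assert len(set(got[members])) == 1
        # border points attach to a cluster containing an adjacent core
        for b in np.flatnonzero((got != -1) & ~core):
            adjacent_cores = np.flatnonzero(adj[b] & core)
            assert got[b] in set(got[adjacent_cores])


class TestMerging:
    def _cluster_map(self, centroids):
        rows = []
        for k, (cx, cy) in enumerate(centroids):
            rows.append({"cell_id": f"m{k}", "x": cx, "y": cy,
                         "cell_type": "B", "CCL19": 1, "CXCL13": 1})
        cm = CellMap(sample_id="m", cells=pd.DataFrame(rows))
        from lymphagg.la_detection import LACluster
        clusters = [LACluster(cluster_id=k, member_ids=[f"m{k}"],
                              centroid=tuple(c)) for k, c in enumerate(centroids)]
        return cm, clusters

    def test_single_cluster_unchanged(self):
        cm, clusters = self._cluster_map([(0, 0)])
        assert len(merge_clusters(clusters, cm)) == 1

    def test_transitive_chain_merges_into_one(self):
        # A-B 390, B-C 390, A-C 780: single-linkage closure joins all three
        cm, clusters = self._cluster_map([(0, 0), (390, 0), (780, 0)])
        merged = merge_clusters(clusters, cm, merge_distance=400)
        assert len(merged) == 1
        assert sorted(merged[0].member_ids) == ["m0", "m1", "m2"]

    def test_boundary_400_merges_401_does_not(self):
        cm, clusters = self._cluster_map([(0, 0), (400.0, 0)])
        assert len(merge_clusters(clusters, cm, merge_distance=400)) == 1
        cm, clusters = self._cluster_map([(0, 0), (401.0, 0)])
        assert len(merge_clusters(clusters, cm, merge_distance=400)) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_connected_components_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cents = rng.uniform(0, 3000, size=(12, 2))
        cm, clusters = self._cluster_map([tuple(c) for c in cents])
        merged = merge_clusters(clusters, cm, merge_distance=400)
        # oracle: union-find over all pairs
        parent = list(range(12))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        for i in range(12):
            for j in range(i + 1, 12):
                if np.hypot(*(cents[i] - cents[j])) <= 400:
                    parent[find(i)] = find(j)
        n_comp = len({find(i) for i in range(12)})
        assert len(merged) == n_comp


class TestPolygons:
    def test_single_point_disc_area(self):
        poly, fb = build_la_polygon(np.array([[10.0, 20.0]]), hull_buffer=100)
        assert poly.area == pytest.approx(np.pi * 100**2, rel=0.01)
        assert not fb

    def test_square_minkowski_sum_area(self):
        corners = np.array([[0, 0], [200, 0], [200, 200], [0, 200]], dtype=float)
        poly, _ = build_la_polygon(corners, hull_buffer=100)
        expected = 200**2 + 4 * 200 * 100 + np.pi * 100**2
        assert poly.area == pytest.approx(expected, rel=0.01)

    def test_two_points_capsule_area(self):
        poly, _ = build_la_polygon(np.array([[0.0, 0.0], [100.0, 0.0]]),
                                   hull_buffer=50)
        assert poly.area == pytest.approx(100 * 100 + np.pi * 50**2, rel=0.01)

    def test_zero_points_rejected(self):
        with pytest.raises(ValidationError):
            build_la_polygon(np.empty((0, 2)))

    @pytest.mark.parametrize("seed", range(20))
    def test_buffered_hull_contains_all_inputs(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 300, size=(40, 2))
        poly, _ = build_la_polygon(pts, hull_buffer=100, hull_alpha=150)
        assert shapely.intersects_xy(poly, pts[:, 0], pts[:, 1]).all()


class TestAssignment:
    def test_cell_on_polygon_edge_is_assigned(self):
        from shapely.geometry import Polygon
        df = pd.DataFrame({"cell_id": ["edge"], "x": [0.0], "y": [5.0],
                           "cell_type": ["B"], "CCL19": [0], "CXCL13": [0]})
        cm = CellMap(sample_id="s", cells=df)
        square = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        memb = assign_cells_to_las(cm, [(0, square, (5.0, 5.0))])
        assert memb["edge"] == 0

    def test_no_polygons_everything_outside(self, tiny_cellmap):
        memb = assign_cells_to_las(tiny_cellmap, [])
        assert (memb == OUTSIDE).all()

    def test_matches_point_in_polygon_scan(self):
        from shapely.geometry import Polygon
        rng = np.random.default_rng(7)
        cm = random_cellmap(rng, n=1000, width=1000)
        polys = [(0, Polygon([(0, 0), (300, 0), (300, 300), (0, 300)]), (150, 150)),
                 (1, Polygon([(600, 600), (950, 600), (950, 950), (600, 950)]),
                  (775, 775))]
        memb = assign_cells_to_las(cm, polys)
        for _, row in cm.cells.iterrows():
            expected = OUTSIDE
            for la_id, poly, _ in polys:
                if poly.covers(shapely.Point(row["x"], row["y"])):
                    expected = la_id
            assert memb[row["cell_id"]] == expected

    def test_overlap_resolved_by_nearest_source_centroid(self):
        from shapely.geometry import Polygon
        df = pd.DataFrame({"cell_id": ["p"], "x": [45.0], "y": [5.0],
                           "cell_type": ["B"], "CCL19": [0], "CXCL13": [0]})
        cm = CellMap(sample_id="s", cells=df)
        a = Polygon([(0, 0), (60, 0), (60, 10), (0, 10)])
        b = Polygon([(40, 0), (100, 0), (100, 10), (40, 10)])
        memb = assign_cells_to_las(cm, [(0, a, (0.0, 5.0)), (1, b, (70.0, 5.0))])
        assert memb["p"] == 1  # centroid of LA 1 is 25 away, LA 0 is 45


# ---------------------------------------------------------------------------
# full pipeline

def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b)


class TestPipeline:
    def test_strict_recovery_of_planted_aggregates(self):
        params = TissueSimParams.strict_recovery_preset(seed=5)
        cm, truth = generate_tissue(params)
        aggs, _ = detect_lymphoid_aggregates(cm)
        assert len(aggs) == 20
        for members in truth.la_member_ids:
            planted = set(members)
            best = max(_jaccard(planted, set(la.member_ids)) for la in aggs)
            assert best >= 0.95

    def test_no_chemokines_no_aggregates(self):
        cm, _ = generate_tissue(TissueSimParams(seed=0, n_las=0,
                                                n_background=500,
                                                chemokine_noise_rate=0.0))
        aggs, memb = detect_lymphoid_aggregates(cm)
        assert aggs == []
        assert (memb == OUTSIDE).all()

    def test_partition_property(self, small_tissue):
        cm, _ = small_tissue
        aggs, memb = detect_lymphoid_aggregates(cm)
        inside = set().union(*[set(la.member_ids) for la in aggs]) if aggs else set()
        outside = set(memb.index[memb == OUTSIDE])
        assert inside | outside == set(cm.cells["cell_id"])
        assert inside & outside == set()
        for la in aggs:
            assert sum(la.counts_by_type.values()) == len(la.member_ids)

    def test_row_order_and_translation_invariance(self, small_tissue):
        cm, _ = small_tissue
        aggs, _ = detect_lymphoid_aggregates(cm)
        base = sorted(frozenset(la.member_ids) for la in aggs)
        shuffled = cm.cells.sample(frac=1.0, random_state=1).reset_index(drop=True)
        cm2 = CellMap(sample_id="shuf", cells=shuffled)
        aggs2, _ = detect_lymphoid_aggregates(cm2)
        assert sorted(frozenset(la.member_ids) for la in aggs2) == base
        moved = cm.cells.copy()
        moved["x"] += 1234.5
        moved["y"] -= 987.25
        cm3 = CellMap(sample_id="moved", cells=moved)
        aggs3, _ = detect_lymphoid_aggregates(cm3)
        assert sorted(frozenset(la.member_ids) for la in aggs3) == base

    def test_every_la_contains_min_cluster_seed_cells(self, small_tissue):
        cm, _ = small_tissue
        cfg = Config()
        seeds = set(select_chemokine_seed_cells(cm))
        aggs, _ = detect_lymphoid_aggregates(cm, cfg)
        assert aggs  # tissue plants 5 LAs
        for la in aggs:
            assert len(seeds & set(la.member_ids)) >= cfg.min_cluster_cells

    @pytest.mark.parametrize("seed", range(5))
    def test_chemokine_noise_does_not_split_planted_las(self, seed):
        quiet = TissueSimParams.strict_recovery_preset(seed=seed, n_las=5)
        noisy = TissueSimParams.strict_recovery_preset(
            seed=seed, n_las=5, strict_recovery=False, chemokine_noise_rate=4.0)
        n_quiet = len(detect_lymphoid_aggregates(generate_tissue(quiet)[0])[0])
        aggs_noisy, _ = detect_lymphoid_aggregates(generate_tissue(noisy)[0])
        # planted LAs stay intact (never split); noise can only add spurious
        # detections, which min_cluster_cells suppresses at this rate
        assert len(aggs_noisy) >= n_quiet == 5
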