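import numpy as np
import pytest

from ndrscape import (
    AnalysisParams,
    ChromSizes,
    NdrscapeError,
    OccupancyTrack,
    RatioMatrix,
    TssRecord,
    ValidationError,
    WindowOutOfBounds,
    extract_window,
    kmeans_cluster,
    order_for_heatmap,
    ratio_matrix,
)
from _oracles import mirror_genome


def track_of(values):
    return OccupancyTrack({"chrI": np.asarray(values, dtype=float)})


class TestExtractWindow:
    def test_plus_strand(self):
        track = track_of(np.arange(20))
        # positions 8..12 = [8..12]; relabel values for clarity
        track.data["chrI"][8:13] = [1, 2, 3, 4, 5]
        out = extract_window(track, TssRecord("g", "chrI", 10, "+"), 2)
        assert out.tolist() == [1, 2, 3, 4, 5]

    def test_minus_strand_reversed(self):
        track = track_of(np.zeros(20))
        track.data["chrI"][8:13] = [1, 2, 3, 4, 5]
        out = extract_window(track, TssRecord("g", "chrI", 10, "-"), 2)
        assert out.tolist() == [5, 4, 3, 2, 1]

    def test_out_of_bounds_signals_exclusion(self):
        track = track_of(np.zeros(20))
        with pytest.raises(WindowOutOfBounds):
            extract_window(track, TssRecord("g", "chrI", 1, "+"), 5)


class TestRatioMatrix:
    def test_identity_gives_zero(self):
        t = track_of(np.full(100, 2.0))
        params = AnalysisParams(flank=10)
        m = ratio_matrix(t, t, [TssRecord("g", "chrI", 50, "+")], params)
        assert np.all(m.values == 0)

    def test_analytic_values(self):
        treat = track_of(np.ones(100))
        ctrl = track_of(np.ones(100))
        treat.data["chrI"][50] = 3.0  # log2((3+1)/(1+1)) = 1
        treat.data["chrI"][51] = 0.0
        ctrl.data["chrI"][51] = 15.0  # log2((0+1)/(15+1)) = -4
        m = ratio_matrix(treat, ctrl, [TssRecord("g", "chrI", 50, "+")], AnalysisParams(flank=5))
        center = 5
        assert m.values[0, center] == 1.0
        assert m.values[0, center + 1] == -4.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = track_of(rng.random(200) * 5)
        b = track_of(rng.random(200) * 5)
        tss = [TssRecord(f"g{i}", "chrI", p, s) for i, (p, s) in
               enumerate([(60, "+"), (100, "-"), (140, "+")])]
        params = AnalysisParams(flank=40)
        ab = ratio_matrix(a, b, tss, params)
        ba = ratio_matrix(b, a, tss, params)
        np.testing.assert_array_equal(ab.values, -ba.values)

    def test_bound(self):
        rng = np.random.default_rng(4)
        a = track_of(rng.random(200) * 9)
        b = track_of(rng.random(200) * 9)
        m = ratio_matrix(a, b, [TssRecord("g", "chrI", 100, "+")], AnalysisParams(flank=50))
        bound = np.log2((9 + 1) / 1)
        assert np.all(np.abs(m.values) <= bound)

    def test_excluded_genes_reported(self):
        t = track_of(np.ones(100))
        tss = [TssRecord("edge", "chrI", 2, "+"), TssRecord("ok", "chrI", 50, "+")]
        m = ratio_matrix(t, t, tss, AnalysisParams(flank=10))
        assert m.gene_ids == ["ok"] and m.excluded == ["edge"]

    def test_no_usable_genes(self):
        t = track_of(np.ones(10))
        with pytest.raises(NdrscapeError):
            ratio_matrix(t, t, [TssRecord("g", "chrI", 0, "+")], AnalysisParams(flank=20))

    def test_mirror_symmetry(self, sim_small):
        from ndrscape import render_occupancy

        params, sizes, tss, truth = sim_small
        wt = render_occupancy(truth, "wt", params, sizes)
        mut = render_occupancy(truth, "mutant", params, sizes)
        ap = AnalysisParams(flank=400)
        m = ratio_matrix(mut, wt, tss, ap)
        mwt, mtss = mirror_genome(wt, sizes, tss)
        mmut, _ = mirror_genome(mut, sizes, tss)
        mm = ratio_matrix(mmut, mwt, mtss, ap)
        np.testing.assert_array_equal(m.values, mm.values)


def two_archetype_matrix(n_per=10, flank=20, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    width = 2 * flank + 1
    coords = np.arange(-flank, flank + 1)
    a = np.where(coords <= 0, 1.0, -0.2)  # upstream gain
    b = np.where(coords <= 0, -1.0, 0.2)  # upstream loss
    rows = np.concatenate(
        [
            a + rng.normal(0, noise_sd, (n_per, width)),
            b + rng.normal(0, noise_sd, (n_per, width)),
        ]
    )
    ids = [f"g{i:03d}" for i in range(2 * n_per)]
    return RatioMatrix(ids, flank, rows)


class TestKmeans:
    def test_two_pure_clusters(self):
        m = two_archetype_matrix()
        params = AnalysisParams(flank=20, k=2, seed=0)
        assignment = kmeans_cluster(m, params)
        labels = [assignment.labels[g] for g in m.gene_ids]
        # canonical renumbering: upstream-gain archetype is cluster 1
        assert labels == [1] * 10 + [2] * 10

    def test_k1_centroid_is_column_mean(self):
        m = two_archetype_matrix()
        assignment = kmeans_cluster(m, AnalysisParams(flank=20, k=1, seed=0))
        assert set(assignment.labels.values()) == {1}

    def test_determinism(self):
        m = two_archetype_matrix(noise_sd=0.3, seed=5)
        params = AnalysisParams(flank=20, k=3, seed=11)
        a = kmeans_cluster(m, params)
        b = kmeans_cluster(m, params)
        assert a.labels == b.labels

    def test_fewer_rows_than_k(self):
        m = two_archetype_matrix(n_per=2)
        with pytest.raises(NdrscapeError):
            kmeans_cluster(m, AnalysisParams(flank=20, k=5, seed=0))


class TestHeatmapOrder:
    def test_boundaries(self):
        m = two_archetype_matrix(n_per=0, flank=2)  # build manually below
        values = np.array([[3.0] * 5, [2.0] * 5, [1.0] * 5, [5.0] * 5, [4.0] * 5])
        m = RatioMatrix(["a", "b", "c", "d", "e"], 2, values)
        from ndrscape.tss_matrix import ClusterAssignment

        clusters = ClusterAssignment(
            {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2}, 2, {1: 0.0, 2: 0.0}
        )
        ordered, boundaries = order_for_heatmap(m, clusters)
        assert ordered == ["a", "b", "c", "d", "e"]
        assert boundaries == [3]

    def test_permutation_invariance(self):
        m = two_archetype_matrix(noise_sd=0.1, seed=2)
        params = AnalysisParams(flank=20, k=2, seed=0)
        clusters = kmeans_cluster(m, params)
        ordered, bounds = order_for_heatmap(m, clusters)
        perm = np.random.default_rng(0).permutation(len(m.gene_ids))
        shuffled = RatioMatrix(
            [m.gene_ids[i] for i in perm], m.flank, m.values[perm]
        )
        ordered2, bounds2 = order_for_heatmap(shuffled, clusters)
        assert ordered == ordered2 and bounds == bounds2
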