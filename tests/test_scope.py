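"""SCOPE peak caller: filtering, KDE, peak calling, clustering, subtraction."""

import numpy as np
import pandas as pd
import pytest

from scopeggs.errors import ScopeggsError
from scopeggs.scope import (
    KdeGrid,
    PairSet,
    ScopeDetector,
    ScopeParams,
    binned_kde_2d,
    call_peak_bins,
    calls_from_clusters,
    cluster_peak_bins,
    filter_by_separation,
    filter_pairs,
    naive_kde_2d,
    run_scope,
    subtract_background,
    summarize_clusters,
)
from scopeggs.tracks import IntervalSet

X_LEN = 70_507_862


def make_pairs(rows, sizes=None):
    df = pd.DataFrame(rows, columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "mapq"])
    return PairSet(df=df, chrom_sizes=sizes or {"chrX": X_LEN})


class TestFilterPairs:
    def test_distance_and_mapq_rules(self):
        ps = make_pairs(
            [
                ("chrX", 1_000_000, "chrX", 7_000_000, 60),  # 6 Mb: kept
                ("chrX", 1_000_000, "chrX", 3_000_000, 60),  # 2 Mb: dropped
                ("chrX", 1_000_000, "chrX", 9_000_000, 5),   # pair MAPQ 5: dropped
            ]
        )
        out = filter_pairs(ps, ScopeParams(min_intermate_distance=5_000_000))
        assert len(out) == 1
        assert out.df.iloc[0]["pos_b"] == 7_000_000

    def test_canonicalization(self):
        ps = make_pairs([("chrX", 9_000_000, "chrX", 2_000_000, 60)])
        out = filter_pairs(ps, ScopeParams())
        assert (out.df["pos_a"] <= out.df["pos_b"]).all()

    def test_intra_only_drops_trans_pairs(self):
        ps = make_pairs(
            [("chrX", 1, "chr2", 2_000_000, 60)],
            sizes={"chrX": X_LEN, "chr2": 10_000_000},
        )
        assert len(filter_pairs(ps, ScopeParams())) == 0
        assert len(filter_pairs(ps, ScopeParams(), intra_only=False)) == 1

    def test_empty_output_allowed(self):
        ps = make_pairs([("chrX", 1, "chrX", 2, 60)])
        assert len(filter_pairs(ps, ScopeParams())) == 0


class TestKde:
    def test_single_point_peak_in_containing_bin(self):
        g = binned_kde_2d([(10.2, 42.7)], (0, 64), 64, (0.3, 0.3))
        i, j = np.unravel_index(np.argmax(g.z), g.z.shape)
        assert (i, j) == (10, 42)

    def test_normalization(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 64, size=(37, 2))
        g = binned_kde_2d(pts, (0, 64), 64, (2.0, 3.0))
        assert g.z.sum() * g.bin_width**2 == pytest.approx(1.0, abs=1e-6)
        assert (g.z >= 0).all()

    def test_binned_matches_naive_oracle(self):
        """Truncation disabled: the accumulated KDE must equal the direct
        O(N·m²) Gaussian-sum oracle to 1e−6 relative."""
        rng = np.random.default_rng(7)
        pts = rng.uniform(5, 59, size=(100, 2))
        gb = binned_kde_2d(pts, (0, 64), 64, (2.5, 3.5), truncation=None)
        gn = naive_kde_2d(pts, (0, 64), 64, (2.5, 3.5))
        assert np.max(np.abs(gb.z - gn.z)) <= 1e-6 * gn.z.max()

    def test_naive_peak_value_closed_form(self):
        """One kernel at a bin center: before grid renormalization the
        density there is 1/(2π·bx·by); with bandwidths well inside the
        extent the renormalization is a ≤0.1% correction."""
        bx, by = 2.0, 3.0
        g = naive_kde_2d([(32.5, 32.5)], (0, 64), 64, (bx, by))
        assert g.z.max() == pytest.approx(1 / (2 * np.pi * bx * by), rel=1e-3)

    def test_naive_reflection_symmetry(self):
        g = naive_kde_2d([(20, 20), (44, 44)], (0, 64), 64, (2, 2))
        assert np.allclose(g.z, g.z[::-1, ::-1], atol=1e-12)

    def test_errors(self):
        with pytest.raises(ScopeggsError):
            binned_kde_2d(np.empty((0, 2)), (0, 64), 64, (1, 1))
        with pytest.raises(ScopeggsError):
            binned_kde_2d([(1, 1)], (0, 64), 64, (0, 1))
        with pytest.raises(ScopeggsError):
            binned_kde_2d([(100, 1)], (0, 64), 64, (1, 1))


def grid_from(z):
    z = np.asarray(z, dtype=float)
    return KdeGrid(chrom="chrX", start=0, end=z.shape[0] * 10.0, m=z.shape[0], z=z)


class TestPeakCalling:
    def test_single_hot_bin(self):
        z = np.zeros((32, 32))
        z[5, 20] = 10.0
        peaks = call_peak_bins(grid_from(z), 0.998)
        assert peaks == [(5, 20, 10.0)]

    def test_constant_grid_yields_no_peaks(self):
        assert call_peak_bins(grid_from(np.ones((16, 16))), 0.998) == []

    def test_row_major_order(self):
        z = np.zeros((8, 8))
        z[6, 1] = z[2, 5] = 9.0
        peaks = call_peak_bins(grid_from(z), 0.9)
        assert [(i, j) for i, j, _ in peaks] == [(2, 5), (6, 1)]

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(3)
        g = grid_from(rng.random((32, 32)))
        sets = [
            {(i, j) for i, j, _ in call_peak_bins(g, q)}
            for q in (0.9, 0.95, 0.99, 0.999)
        ]
        for smaller, larger in zip(sets[1:], sets[:-1]):
            assert smaller <= larger


class TestClustering:
    def test_k1_collects_everything(self):
        g = grid_from(np.zeros((16, 16)))
        peaks = [(1, 2, 1.0), (10, 12, 2.0), (14, 3, 3.0)]
        (cluster,) = cluster_peak_bins(peaks, 1, g)
        assert len(cluster) == 3

    def test_three_separated_blobs(self):
        g = KdeGrid("chrX", 0, 1000.0, 100, np.zeros((100, 100)))
        blobs = {
            0: [(2, 3, 1.0), (3, 3, 1.0), (3, 4, 1.0)],
            1: [(50, 60, 1.0), (51, 60, 1.0)],
            2: [(90, 10, 1.0), (91, 11, 1.0)],
        }
        peaks = [p for b in blobs.values() for p in b]
        clusters = cluster_peak_bins(peaks, 3, g)
        got = {frozenset((i, j) for i, j, _ in c) for c in clusters}
        want = {frozenset((i, j) for i, j, _ in b) for b in blobs.values()}
        assert got == want

    def test_identical_coordinates_zero_span(self):
        g = grid_from(np.zeros((16, 16)))
        (cluster,) = cluster_peak_bins([(4, 8, 1.0)] * 3, 1, g)
        (summary,) = summarize_clusters([cluster], g)
        assert summary.min_x == summary.max_x == summary.median_x

    def test_fewer_peaks_than_k(self):
        with pytest.raises(ScopeggsError):
            cluster_peak_bins([(0, 0, 1.0)], 2, grid_from(np.zeros((8, 8))))

    def test_permutation_invariant(self):
        g = KdeGrid("chrX", 0, 1000.0, 100, np.zeros((100, 100)))
        peaks = [(2, 3, 1.0), (3, 3, 2.0), (50, 60, 1.0), (51, 60, 2.0)]
        a = cluster_peak_bins(peaks, 2, g)
        b = cluster_peak_bins(peaks[::-1], 2, g)
        assert {frozenset(c) for c in a} == {frozenset(c) for c in b}


class TestSummaries:
    def test_single_bin_cluster(self):
        g = grid_from(np.zeros((16, 16)))
        (s,) = summarize_clusters([[(4, 8, 2.5)]], g)
        assert s.median_x == s.min_x == s.max_x == g.bin_center(4)
        assert s.summit == (g.bin_center(4), g.bin_center(8), 2.5)

    def test_odd_and_even_median_conventions(self):
        g = KdeGrid("chrX", 0, 100e6, 100, np.zeros((100, 100)))
        # centers at 10.5, 20.5, 30.5 Mb → median 20.5
        (s,) = summarize_clusters([[(10, 0, 1.0), (20, 0, 1.0), (30, 0, 1.0)]], g)
        assert s.median_x == pytest.approx(20.5e6)
        (s2,) = summarize_clusters(
            [[(10, 0, 1.0), (20, 0, 1.0), (30, 0, 1.0), (40, 0, 1.0)]], g
        )
        assert s2.median_x == pytest.approx(25.5e6)  # midpoint of 20.5 / 30.5

    def test_summit_tie_breaks_to_smaller_row_major(self):
        g = grid_from(np.zeros((16, 16)))
        (s,) = summarize_clusters([[(3, 9, 5.0), (2, 11, 5.0)]], g)
        assert s.summit[:2] == (g.bin_center(2), g.bin_center(11))

    def test_separation_filter(self):
        g = KdeGrid("chrX", 0, 100e6, 100, np.zeros((100, 100)))
        near = summarize_clusters([[(10, 12, 1.0)]], g)[0]   # 2 Mb apart
        far = summarize_clusters([[(10, 40, 1.0)]], g)[0]    # 30 Mb apart
        kept = filter_by_separation([near, far], 5_000_000)
        assert kept == [far]


class TestBackgroundSubtraction:
    def _call(self, x1, x2, y1, y2):
        g = KdeGrid("chrX", 0, 100e6, 100, np.zeros((100, 100)))
        members = [(i, j, 1.0) for i in range(x1, x2) for j in range(y1, y2)]
        return calls_from_clusters(summarize_clusters([members], g), g)[0]

    def test_identical_control_removes_call(self):
        call = self._call(10, 12, 40, 42)
        assert subtract_background([call], [self._call(10, 12, 40, 42)], None, 0) == []

    def test_disjoint_control_keeps_call(self):
        call = self._call(10, 12, 40, 42)
        kept = subtract_background([call], [self._call(70, 72, 90, 92)], None, 0)
        assert kept == [call]

    def test_swapped_anchor_order_still_matches(self):
        call = self._call(10, 12, 40, 42)
        ctl = self._call(10, 12, 40, 42)
        ctl.anchor_1, ctl.anchor_2 = ctl.anchor_2, ctl.anchor_1
        assert subtract_background([call], [ctl], None, 0) == []

    def test_sv_breakpoint_overlap_removes(self):
        call = self._call(10, 12, 40, 42)
        svs = IntervalSet(pd.DataFrame({"chrom": ["chrX"], "start": [10_500_000], "end": [10_600_000]}))
        assert subtract_background([call], [], svs, 0) == []
        far = IntervalSet(pd.DataFrame({"chrom": ["chrX"], "start": [80_000_000], "end": [80_100_000]}))
        assert subtract_background([call], [], far, 0) == [call]


class TestRunScope:
    def test_recovers_planted_interactions(self, demo_sim):
        cfg, pairs = demo_sim
        calls, log = run_scope(pairs, ScopeParams())
        assert log["n_calls"] == 4
        truth = [(l.anchor_x, l.anchor_y) for l in cfg.loops]
        h = X_LEN / 1024
        for c in calls:
            best = min(truth, key=lambda t: abs(t[0] - c.median_x) + abs(t[1] - c.median_y))
            assert abs(c.median_x - best[0]) <= 2 * h
            assert abs(c.median_y - best[1]) <= 2 * h

    def test_no_pairs_passing_filters(self):
        ps = make_pairs([("chrX", 1, "chrX", 100, 60)])
        calls, log = run_scope(ps, ScopeParams(), chrom="chrX")
        assert calls == [] and "warning" in log

    def test_pair_order_invariance(self, demo_sim):
        _, pairs = demo_sim
        shuffled = PairSet(
            df=pairs.df.sample(frac=1.0, random_state=0).reset_index(drop=True),
            chrom_sizes=pairs.chrom_sizes,
        )
        c1, _ = run_scope(pairs, ScopeParams())
        c2, _ = run_scope(shuffled, ScopeParams())
        a1 = sorted((c.anchor_1.start, c.anchor_2.start) for c in c1)
        a2 = sorted((c.anchor_1.start, c.anchor_2.start) for c in c2)
        assert a1 == a2

    def test_run_log_records_parameters(self, demo_sim):
        _, pairs = demo_sim
        _, log = run_scope(pairs, ScopeParams(k_clusters=12))
        assert log["params"]["k_clusters"] == 12
        assert log["n_pairs_in"] == len(pairs)


class TestScopeDetector:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        det = ScopeDetector(peak_quantile=0.995, k_clusters=6)
        params = det.get_params()
        assert params["peak_quantile"] == 0.995
        cloned = clone(det)
        assert cloned.get_params() == params
        det.set_params(k_clusters=4)
        assert det.k_clusters == 4

    def test_fit_exposes_calls_and_grid(self, demo_sim):
        _, pairs = demo_sim
        det = ScopeDetector().fit(pairs)
        assert det.n_calls_ == 4
        assert det.grid_.m == 1024
        assert det.runlog_["n_calls"] == 4
        assert det.fit_predict(pairs) == det.calls_

    def test_grid_bin_width_matches_published_values(self):
        g = KdeGrid("chrX", 0, X_LEN, 1024, np.zeros((1, 1)))
        assert g.bin_width == pytest.approx(68_855.3, abs=0.05)
        g2 = KdeGrid("chrX", 0, X_LEN, 2048, np.zeros((1, 1)))
        assert g2.bin_width == pytest.approx(34_427.7, abs=0.05)
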