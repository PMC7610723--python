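"""Trace analysis: segment precision, clustering, filters, rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from minsted import (LocalizerParams, PhotonScene, RenderConfig, SegmentSpec,
                     cluster_localizations, filter_localizations,
                     fit_loglog_slope, render_image,
                     repeated_localization_stats, run_ensemble,
                     segment_precision)


def _trace_from(positions, d=40.0):
    pos = np.asarray(positions, dtype=float)
    return pd.DataFrame({"i": np.arange(1, len(pos) + 1), "phi": 0.0,
                         "Cx": pos[:, 0], "Cy": pos[:, 1],
                         "R": d / 2, "d": d})


def _floor_trace(params, N, seed, sbr=20.0):
    """One simulated floor-phase centre trace of length N."""
    run = run_ensemble(PhotonScene(sbr=sbr), params,
                       N, 1, rng=np.random.default_rng(seed))
    C = run.C[0, run.N_c - 1:, :]
    return _trace_from(C, d=params.d_min)


class TestSegmentPrecision:
    def test_constant_trace_gives_zero(self):
        trace = _trace_from([(3.0, -1.0)] * 200)
        for M in (2, 10, 50):
            assert segment_precision(trace, SegmentSpec(M=M)) == 0.0

    def test_iid_gaussian_scaling(self, rng):
        # i.i.d. Gaussian centres with per-axis std s: segment means have
        # std s/sqrt(M)
        s, M, n = 5.0, 25, 20000
        trace = _trace_from(rng.normal(0, s, size=(n, 2)))
        got = segment_precision(trace, SegmentSpec(M=M))
        assert got == pytest.approx(s / math.sqrt(M), rel=0.1)

    def test_simulated_walk_follows_inverse_sqrt_M(self, params):
        trace = _floor_trace(params, 64 + 12000, seed=8)
        Ms = [25, 50, 100, 200, 400]
        sig = [segment_precision(trace, SegmentSpec(M=M)) for M in Ms]
        slope = fit_loglog_slope(Ms, sig)
        assert slope == pytest.approx(-0.5, abs=0.07)

    def test_rescaled_curves_collapse_across_floors(self):
        # sigma_M scaled to a 200 nm floor overlays for d_min in {40,100,200}
        Ms = [50, 200]
        curves = {}
        for j, d_min in enumerate((40.0, 100.0, 200.0)):
            params = LocalizerParams(d_min=d_min)
            from minsted import steps_to_dmin
            trace = _floor_trace(params, steps_to_dmin(params) + 8000,
                                 seed=40 + j)
            curves[d_min] = [(200.0 / d_min) * segment_precision(
                trace, SegmentSpec(M=M)) for M in Ms]
        for k in range(len(Ms)):
            vals = [curves[d][k] for d in curves]
            assert max(vals) / min(vals) < 1.35

    def test_short_trace_error_names_the_shortfall(self):
        trace = _trace_from([(0.0, 0.0)] * 30)
        with pytest.raises(ValueError, match="30 floor-phase"):
            segment_precision(trace, SegmentSpec(M=20))


class TestClustering:
    @staticmethod
    def _table(points):
        pts = np.asarray(points, dtype=float)
        return pd.DataFrame({"Cx": pts[:, 0], "Cy": pts[:, 1]})

    def test_threshold_boundary(self):
        near = cluster_localizations(self._table([(0, 0), (24, 0)]), min_size=1)
        far = cluster_localizations(self._table([(0, 0), (26, 0)]), min_size=1)
        assert near["cluster"].nunique() == 1
        assert far["cluster"].nunique() == 2

    def test_seven_coincident_points_retained(self):
        out = cluster_localizations(self._table([(5.0, 5.0)] * 7))
        assert out["cluster"].nunique() == 1
        assert out["retained"].all()

    def test_small_clusters_flagged_excluded(self):
        out = cluster_localizations(
            self._table([(0, 0)] * 7 + [(500, 500)] * 3))
        by = out.groupby("cluster")["retained"].agg(["size", "first"])
        assert set(map(tuple, by.to_numpy())) == {(7, True), (3, False)}

    def test_empty_table(self):
        out = cluster_localizations(self._table(np.empty((0, 2))))
        assert len(out) == 0 and "cluster" in out.columns

    def test_matches_brute_force_single_linkage(self, rng):
        # independent O(n^2) oracle: union-find over all pairs <= radius
        pts = rng.uniform(0, 300, size=(200, 2))
        out = cluster_localizations(self._table(pts), link_radius=25.0,
                                    min_size=1)
        parent = list(range(len(pts)))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.hypot(*(pts[i] - pts[j])) <= 25.0:
                    parent[find(i)] = find(j)
        oracle = np.array([find(i) for i in range(len(pts))])
        got = out["cluster"].to_numpy()
        # same partition: labels agree up to renaming
        assert len(set(zip(got, oracle))) == len(set(got)) == len(set(oracle))


class TestFilter:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["N", "Nc", "sigma_hat"]).assign(
            Cx=0.0, Cy=0.0)

    def test_nothing_dropped_when_all_bright_and_sharp(self):
        t = self._table([(400, 64, 1.0)] * 5)
        kept, report = filter_localizations(t, min_tail_detections=250,
                                            max_sigma=5.0)
        assert len(kept) == 5 and report["n_dropped_dim"] == 0

    def test_exact_drop_counts_on_constructed_table(self):
        # 4 dim, 2 excessive-sigma among the bright, 6 kept
        rows = ([(200, 64, 1.0)] * 4 + [(400, 64, 9.0)] * 2
                + [(400, 64, 1.0)] * 6)
        kept, report = filter_localizations(self._table(rows),
                                            min_tail_detections=250,
                                            max_sigma=5.0)
        assert report["n_input"] == 12
        assert report["n_dropped_dim"] == 4
        assert report["n_dropped_sigma"] == 2
        assert report["n_kept"] == len(kept) == 6
        assert report["frac_dropped_dim"] == pytest.approx(4 / 12)

    def test_row_failing_both_rules_counts_as_dim(self):
        rows = [(100, 64, 99.0), (400, 64, 1.0), (400, 64, 1.0)]
        _, report = filter_localizations(self._table(rows),
                                         min_tail_detections=250,
                                         max_sigma=5.0)
        assert report["n_dropped_dim"] == 1
        assert report["n_dropped_sigma"] == 0

    def test_default_sigma_cutoff_is_three_medians(self):
        rows = [(400, 64, 1.0)] * 9 + [(400, 64, 4.0)]
        kept, report = filter_localizations(self._table(rows),
                                            min_tail_detections=250)
        assert report["max_sigma"] == pytest.approx(3.0)
        assert report["n_dropped_sigma"] == 1

    def test_idempotent(self):
        rows = ([(200, 64, 1.0)] * 3 + [(400, 64, 9.0)] + [(400, 64, 1.0)] * 8)
        once, _ = filter_localizations(self._table(rows),
                                       min_tail_detections=250, max_sigma=5.0)
        twice, report = filter_localizations(once, min_tail_detections=250,
                                             max_sigma=5.0)
        pd.testing.assert_frame_equal(once, twice)
        assert report["n_dropped_dim"] == report["n_dropped_sigma"] == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            filter_localizations(pd.DataFrame({"Cx": [1.0]}))


class TestRepeatedLocalizations:
    def test_distinct_positions_and_scans_give_zero(self):
        t = pd.DataFrame({"scan": [0, 10, 20, 30],
                          "Cx": [0.0, 500.0, 1000.0, 1500.0],
                          "Cy": [0.0, 0.0, 0.0, 0.0]})
        out = repeated_localization_stats(t)
        assert out["frac_within_window"] == 0.0

    def test_constructed_repeats_counted_exactly(self):
        # 10 consecutive-scan repeats at 5 nm plus 10 isolated events:
        # 10/19 pairs are within the window, all of them within 20 nm,
        # none within 2 nm
        rows = []
        scan = 0
        for k in range(10):
            rows.append((scan, 1000.0 * k, 0.0))
            rows.append((scan + 1, 1000.0 * k + 5.0, 0.0))
            scan += 20
        t = pd.DataFrame(rows, columns=["scan", "Cx", "Cy"])
        out = repeated_localization_stats(t, window=2, radii=[20.0, 2.0])
        assert out["n_pairs"] == 19
        assert out["frac_within_window"] == pytest.approx(10 / 19)
        assert out["frac_within_radius"][20.0] == 1.0
        assert out["frac_within_radius"][2.0] == 0.0

    def test_radii_validation(self):
        t = pd.DataFrame({"scan": [0, 1], "Cx": [0.0, 1.0], "Cy": [0.0, 0.0]})
        with pytest.raises(ValueError):
            repeated_localization_stats(t, radii=[2.0, 20.0])
        with pytest.raises(ValueError):
            repeated_localization_stats(t, radii=[-1.0])
        with pytest.raises(KeyError):
            repeated_localization_stats(t.drop(columns="scan"))


class TestRendering:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["Cx", "Cy", "sigma_hat"])

    def test_precision_floor_widens_sharp_localizations(self):
        # a 1 nm localization renders with the 3 nm floor: the radial second
        # moment of the image recovers sigma = 3 nm
        cfg = RenderConfig(pixel_size=0.5, sigma_floor=3.0,
                           field=(-30.0, 30.0, -30.0, 30.0))
        img = render_image(self._table([(0.0, 0.0, 1.0)]), cfg)
        ny, nx = img.shape
        xs = -30.0 + 0.5 * (np.arange(nx) + 0.5)
        ys = -30.0 + 0.5 * (np.arange(ny) + 0.5)
        X, Y = np.meshgrid(xs, ys)
        var = float((img * (X ** 2 + Y ** 2)).sum() / img.sum() / 2)
        # discrete pixel integration adds pixel_size^2/12 per axis
        sigma_fit = math.sqrt(var - 0.5 ** 2 / 12)
        assert sigma_fit == pytest.approx(3.0, abs=0.05)

    def test_mass_conservation_two_localizations(self):
        cfg = RenderConfig(pixel_size=2.0, sigma_floor=3.0,
                           field=(0.0, 200.0, 0.0, 200.0))
        img = render_image(self._table([(50.0, 50.0, 2.0),
                                        (150.0, 150.0, 4.0)]), cfg)
        assert float(img.sum()) == pytest.approx(2.0, rel=1e-6)

    def test_translation_equivariance(self):
        cfg = RenderConfig(pixel_size=2.0, sigma_floor=3.0,
                           field=(0.0, 100.0, 0.0, 100.0))
        a = render_image(self._table([(40.0, 30.0, 3.0)]), cfg)
        b = render_image(self._table([(42.0, 30.0, 3.0)]), cfg)
        np.testing.assert_allclose(b[:, 1:], a[:, :-1], atol=1e-7)

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError):
            RenderConfig(field=(0.0, 0.0, 0.0, 10.0))

    def test_empty_table_renders_zeros(self):
        cfg = RenderConfig(field=(0.0, 20.0, 0.0, 20.0))
        img = render_image(self._table([]), cfg)
        assert img.shape == (10, 10) and img.sum() == 0.0


class TestRingRecovery:
    def test_full_pipeline_recovers_ring_radius(self, params, model):
        # synthetic ring of 8 emitters (50 nm radius) standing in for
        # ring-like protein assemblies: simulate -> localize -> filter ->
        # cluster -> fit; the fitted radius recovers 50 nm within
        # 2 * sigma / sqrt(8)
        from minsted import EmitterLayout, generate_scene_ensemble, run_localization
        from minsted.io import records_to_table

        layout = EmitterLayout(kind="ring", n_emitters=8, ring_radius=50.0,
                               sbr=20.0, sigma0=60.0)
        scenes = generate_scene_ensemble(layout, seed=6)
        records = [run_localization(s, params, model, N=400)[0] for s in scenes]
        table = records_to_table(records)
        kept, _ = filter_localizations(table, min_tail_detections=250,
                                       max_sigma=5.0)
        clustered = cluster_localizations(kept, link_radius=25.0, min_size=1)
        assert len(clustered) == 8
        pos = clustered[["Cx", "Cy"]].to_numpy()
        centre = pos.mean(axis=0)
        radii = np.hypot(*(pos - centre).T)
        sigma = params.precision_kappa * params.d_min / math.sqrt(400 - 64 + 1)
        assert radii.mean() == pytest.approx(50.0, abs=2 * sigma / math.sqrt(8))
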