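import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromotrace import localizations as lp
from chromotrace import synth

from conftest import brute_force_dbscan


def make_table(x, y, z, frame, lat=11.0, ax=47.0):
    n = len(x)
    return pd.DataFrame({
        "x_nm": x, "y_nm": y, "z_nm": z, "frame": frame,
        "psf_photons": np.full(n, 500.0), "cutout_photons": np.full(n, 900.0),
        "z_offset_nm": np.zeros(n), "lat_prec_nm": np.full(n, lat),
        "ax_prec_nm": np.full(n, ax), "round": np.ones(n, dtype=int),
    })


class TestScoreQuality:
    @pytest.mark.parametrize("metrics, expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((1.0, 1.0, 0.512), 0.8),   # cube root lands exactly on the cutoff
        ((0.0, 0.9, 0.9), 0.0),
    ])
    def test_geometric_mean(self, metrics, expected):
        assert lp.score_quality(*metrics) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(lp.InvalidMetricError):
            lp.score_quality(1.2, 0.5, 0.5)
        with pytest.raises(lp.InvalidMetricError):
            lp.score_quality(-0.1, 0.5, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_and_monotone(self, a, b, c):
        s = lp.score_quality(a, b, c)
        assert s == pytest.approx(lp.score_quality(c, a, b))
        # raising any metric never lowers the rank
        assert lp.score_quality(min(a + 0.1, 1.0), b, c) >= s - 1e-12


class TestMergeRepeats:
    def test_consecutive_identical_events_merge(self):
        t = make_table([0, 0], [0, 0], [0, 0], [10, 11])
        assert len(lp.merge_repeats(t)) == 1

    def test_frame_span_boundary(self):
        # span 8 frames exceeds the 7-frame window: two separate events
        t = make_table([0, 0], [0, 0], [0, 0], [10, 18])
        assert len(lp.merge_repeats(t)) == 2
        # 7 consecutive frames in a row collapse to one event
        t = make_table(np.zeros(7), np.zeros(7), np.zeros(7), np.arange(10, 17))
        assert len(lp.merge_repeats(t)) == 1
        # an 8th consecutive frame exceeds the span and starts a new event
        t = make_table(np.zeros(8), np.zeros(8), np.zeros(8), np.arange(10, 18))
        assert len(lp.merge_repeats(t)) == 2

    def test_distance_boundary(self):
        # 3 pixels (300 nm) exceeds the 2-pixel radius
        t = make_table([0, 300], [0, 0], [0, 0], [10, 11])
        assert len(lp.merge_repeats(t)) == 2

    def test_gap_breaks_run(self):
        # same position but a 2-frame gap ends the blinking event
        t = make_table([0, 0], [0, 0], [0, 0], [10, 13])
        assert len(lp.merge_repeats(t)) == 2

    def test_merged_position_is_precision_weighted(self):
        t = make_table([0.0, 100.0], [0, 0], [0, 0], [1, 2])
        t.loc[0, "lat_prec_nm"] = 10.0
        t.loc[1, "lat_prec_nm"] = 20.0
        out = lp.merge_repeats(t)
        w = np.array([1 / 100, 1 / 400])
        assert out["x_nm"].iloc[0] == pytest.approx(100 * w[1] / w.sum())
        assert out["psf_photons"].iloc[0] == pytest.approx(1000.0)

    def test_idempotent_and_never_grows(self, rng):
        n = 200
        t = make_table(rng.uniform(0, 5000, n), rng.uniform(0, 5000, n),
                       rng.uniform(0, 500, n), np.sort(rng.integers(0, 500, n)))
        once = lp.merge_repeats(t)
        assert len(once) <= n
        twice = lp.merge_repeats(once)
        assert len(twice) == len(once)
        np.testing.assert_allclose(twice["x_nm"], once["x_nm"])

    def test_requires_frame_order(self):
        t = make_table([0, 0], [0, 0], [0, 0], [5, 3])
        with pytest.raises(ValueError, match="sorted"):
            lp.merge_repeats(t)


class TestFilterAxial:
    def test_threshold_is_inclusive(self):
        t = make_table(np.zeros(4), np.zeros(4), np.zeros(4), np.arange(4))
        t["ax_prec_nm"] = [40.0, 99.0, 100.0, 101.0]
        out = lp.filter_axial(t)
        assert sorted(out["ax_prec_nm"]) == [40.0, 99.0, 100.0]

    def test_typical_precisions_pass(self):
        t = make_table(np.zeros(5), np.zeros(5), np.zeros(5), np.arange(5), ax=47.0)
        assert len(lp.filter_axial(t)) == 5

    def test_empty_input(self):
        t = make_table([], [], [], [])
        assert len(lp.filter_axial(t)) == 0


class TestDriftCorrect:
    def test_static_fiducials_change_nothing(self):
        frames = np.arange(5000)
        track = lp.FiducialTrack("F1", frames, np.tile([100.0, 0, 0], (5000, 1)))
        t = make_table([0.0, 10.0], [0, 0], [0, 0], [100, 4000])
        out, trace = lp.drift_correct(t, [track])
        np.testing.assert_allclose(out["x_nm"], t["x_nm"])
        assert np.abs(trace[["dx_nm", "dy_nm", "dz_nm"]].to_numpy()).max() == 0

    def test_linear_drift_recovered(self):
        n_frames = 10_000
        v = np.array([60.0, -40.0, 25.0])  # total drift over the recording
        frames = np.arange(n_frames)
        frac = frames / (n_frames - 1)
        tracks = [lp.FiducialTrack(f"F{k}", frames,
                                   np.array([k * 500.0, 0, 0]) + frac[:, None] * v)
                  for k in range(3)]
        t = make_table(np.zeros(20), np.zeros(20), np.zeros(20),
                       np.linspace(0, n_frames - 1, 20).astype(int))
        drifted = t.copy()
        drifted[["x_nm", "y_nm", "z_nm"]] += frac[t["frame"]][:, None] * v
        out, trace = lp.drift_correct(drifted, tracks)
        # static emitter recovered up to the first-window offset
        for c in ("x_nm", "y_nm", "z_nm"):
            assert out[c].std() < 2.0
        centers = trace["window_center"].to_numpy()
        expected = (centers[:, None] / (n_frames - 1)) * v
        expected -= expected[0]
        np.testing.assert_allclose(
            trace[["dx_nm", "dy_nm", "dz_nm"]].to_numpy(), expected, atol=1e-6)

    def test_roundtrip_exact(self, rng):
        n_frames = 4000
        frames = np.arange(n_frames)
        pos = np.cumsum(rng.normal(scale=0.5, size=(n_frames, 3)), axis=0)
        tracks = [lp.FiducialTrack("F1", frames, pos + 100.0)]
        t = make_table(rng.uniform(0, 1000, 50), rng.uniform(0, 1000, 50),
                       rng.uniform(0, 500, 50), rng.integers(0, n_frames, 50))
        out, trace = lp.drift_correct(t, tracks)
        back = lp.apply_drift(out, trace)
        np.testing.assert_allclose(
            back[["x_nm", "y_nm", "z_nm"]].to_numpy(),
            t[["x_nm", "y_nm", "z_nm"]].to_numpy(), atol=1e-6)

    def test_no_fiducials_is_an_error(self):
        t = make_table([0.0], [0.0], [0.0], [0])
        with pytest.raises(ValueError):
            lp.drift_correct(t, [])


class TestExtractClusters:
    def test_two_blobs_one_micron_apart(self, rng):
        a = rng.normal(scale=40, size=(100, 3))
        b = rng.normal(scale=40, size=(80, 3)) + [1000.0, 0, 0]
        t = make_table(*np.vstack([a, b]).T, np.arange(180))
        clusters = [c for c in lp.extract_clusters(t) if not c.is_noise]
        assert len(clusters) == 2
        assert len(clusters[0]) >= len(clusters[1])  # sorted by size

    def test_sparse_points_are_all_noise(self):
        grid = np.arange(5) * 400.0  # pairwise >> 150 nm
        xx, yy, zz = np.meshgrid(grid, grid, grid)
        t = make_table(xx.ravel(), yy.ravel(), zz.ravel(), np.arange(125))
        clusters = lp.extract_clusters(t, min_points=3)
        assert all(c.is_noise for c in clusters)

    def test_matches_brute_force_oracle(self, rng):
        pts = np.vstack([
            rng.normal(scale=60, size=(150, 3)),
            rng.normal(scale=60, size=(150, 3)) + [800, 0, 0],
            rng.uniform(-1500, 1500, size=(100, 3)),
        ])
        t = make_table(*pts.T, np.arange(len(pts)))
        eps, min_pts = 150.0, 10
        got = np.full(len(pts), -1)
        for c in lp.extract_clusters(t, eps, min_pts):
            got[c.events.index] = c.label
        want, core = brute_force_dbscan(pts, eps, min_pts)
        # core memberships agree as a partition; noise agrees exactly
        for lab in set(want[core]):
            members = set(np.flatnonzero(core & (want == lab)))
            got_labs = {got[m] for m in members}
            assert len(got_labs) == 1 and -1 not in got_labs
        np.testing.assert_array_equal(got == -1, want == -1)


def test_full_processing_chain_recovers_planted_drift(rng):
    chain = synth.make_chain(20, bond_length=40, confinement_radius=300, seed=rng)
    drift = np.array([50.0, -30.0, 20.0])
    df, tracks = synth.simulate_localizations(
        chain, events_per_bead=60, drift_nm=drift, background_fraction=0.05,
        seed=rng)
    clusters, trace = lp.process(df, fiducials=tracks)
    main = next(c for c in clusters if not c.is_noise)
    assert len(main) > 100
    # recovered drift trace matches the planted linear ramp within 2 nm RMS
    n_frames = 20_000
    centers = trace["window_center"].to_numpy()
    expected = (centers[:, None] / (n_frames - 1)) * drift
    expected -= expected[0]
    resid = trace[["dx_nm", "dy_nm", "dz_nm"]].to_numpy() - expected
    assert np.sqrt((resid ** 2).mean()) < 2.0
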