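"""Localization table I/O, filtering, fiducials, drift and rendering."""

import io

import numpy as np
import pandas as pd
import pytest

from aggpaint import (
    AcquisitionMeta,
    SceneSpec,
    read_localizations,
    write_localizations,
    filter_localizations,
    detect_fiducials,
    estimate_drift,
    apply_drift,
    render_superres,
    simulate_paint,
)
from aggpaint.localizations import remove_fiducials


META100 = AcquisitionMeta(pixel_size_nm=100.0)


class TestReadWrite:
    def test_pixel_units_converted_to_nm(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text("frame,x,y,precision,signal\n0,1.5,2.0,10,50\n1,2.5,0.5,12,60\n2,0.1,0.2,8,70\n")
        t = read_localizations(p, META100, units="px")
        assert np.allclose(t["x_nm"], [150.0, 250.0, 10.0])
        assert np.allclose(t["y_nm"], [200.0, 50.0, 20.0])
        assert len(t) == 3

    def test_header_only_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("frame,x,y,precision,signal,background\n")
        t = read_localizations(p, META100, units="nm")
        assert len(t) == 0

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,x,y,signal\n0,1,2,50\n")
        with pytest.raises(ValueError, match="precision"):
            read_localizations(p, META100)

    def test_non_numeric_cell_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,x,y,precision,signal\n0,1,2,10,50\n1,oops,2,10,50\n")
        with pytest.raises(ValueError, match=r"line\(s\) \[3\]"):
            read_localizations(p, META100, units="nm")
        t = read_localizations(p, META100, units="nm", on_malformed="drop")
        assert len(t) == 1

    def test_write_read_round_trip(self, tmp_path):
        spec = SceneSpec(n_fibrils=2)
        locs, _ = simulate_paint(spec, seed=3)
        p = tmp_path / "rt.csv"
        write_localizations(locs, p)
        back = read_localizations(p, spec.meta, units="nm")
        assert (back["frame"] == locs["frame"]).all()
        for col in ("x_nm", "y_nm", "precision_nm", "signal"):
            assert np.allclose(back[col], locs[col], rtol=1e-9)


class TestFilter:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "frame": range(10),
                "x_nm": np.linspace(0, 90, 10),
                "y_nm": np.zeros(10),
                "precision_nm": [5, 10, 25.0, 25.1, 30, 8, 12, 40, 24.9, 3],
                "signal": [40, 39, 100, 200, 50, 45, 38, 500, 41, 40],
                "background": np.zeros(10),
            }
        )

    def test_boundaries_inclusive(self, table):
        out = filter_localizations(table)
        # row 0: signal 40 (kept, boundary), precision 5 -> kept
        assert 0 in out["frame"].values
        # row 2: precision exactly 25.0 -> kept
        assert 2 in out["frame"].values
        # row 3: precision 25.1 -> dropped; row 1: signal 39 -> dropped
        assert 3 not in out["frame"].values and 1 not in out["frame"].values

    def test_all_below_signal_threshold_gives_empty(self, table):
        t = table.assign(signal=39.0)
        assert len(filter_localizations(t)) == 0

    def test_matches_row_by_row_oracle_and_is_idempotent(self, table):
        expect = [
            i
            for i, r in table.iterrows()
            if r["signal"] >= 40 and r["precision_nm"] <= 25
        ]
        out = filter_localizations(table)
        assert list(out["frame"]) == [table.loc[i, "frame"] for i in expect]
        again = filter_localizations(out)
        pd.testing.assert_frame_equal(out, again)


def _fiducial_table(n_frames, x=1000.0, y=2000.0, extra=None):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "x_nm": x + rng.normal(0, 2, n_frames),
            "y_nm": y + rng.normal(0, 2, n_frames),
            "precision_nm": 2.0,
            "signal": 5e4,
            "background": 0.0,
        }
    )
    if extra is not None:
        df = pd.concat([df, extra], ignore_index=True)
    return df


class TestFiducials:
    def test_marker_in_every_frame_is_one_track(self):
        t = _fiducial_table(4000)
        tracks = detect_fiducials(t)
        assert len(tracks) == 1
        assert tracks[0]["span_frames"] == 4000

    def test_exactly_100_frames_is_not_a_fiducial(self):
        # "more than 100 frames" is strict
        t = _fiducial_table(100)
        assert detect_fiducials(t) == []
        t101 = _fiducial_table(101)
        assert len(detect_fiducials(t101)) == 1

    def test_three_planted_fiducials_recovered_in_full_scene(self, default_scene):
        spec, locs, truth = default_scene
        tracks = detect_fiducials(filter_localizations(locs))
        assert len(tracks) == spec.n_fiducials
        found = np.array([t["centroid_nm"] for t in tracks])
        true_fid = locs[(truth.provenance["kind"] == "fiducial").to_numpy()]
        # every track centroid lies near some fiducial localization cloud
        fx = true_fid["x_nm"].to_numpy()
        fy = true_fid["y_nm"].to_numpy()
        for cx, cy in found:
            assert np.min(np.hypot(fx - cx, fy - cy)) < 100


class TestDrift:
    def _scene(self, profile, seed=5, **kw):
        spec = SceneSpec(
            n_fibrils=0,
            background_rate=0.0,
            n_fiducials=kw.pop("n_fiducials", 3),
            drift_profile=profile,
            **kw,
        )
        return spec, *simulate_paint(spec, seed=seed)

    def test_stationary_fiducials_give_near_zero_drift(self):
        spec, locs, truth = self._scene("none")
        tracks = detect_fiducials(locs)
        drift = estimate_drift(locs, tracks, spec.meta.n_frames)
        sigma = locs["precision_nm"].median() / np.sqrt(len(tracks))
        assert np.abs(drift[["dx_nm", "dy_nm"]].to_numpy()).max() < 3 * sigma

    def test_planted_linear_drift_recovered(self):
        spec, locs, truth = self._scene("linear", drift_rate_nm_per_frame=(0.05, 0.0))
        tracks = detect_fiducials(locs)
        drift = estimate_drift(locs, tracks, spec.meta.n_frames)
        endpoint = drift.iloc[-1]
        sigma = locs["precision_nm"].median() / np.sqrt(len(tracks))
        # ~200 nm planted endpoint displacement
        assert abs(endpoint["dx_nm"] - 0.05 * (spec.meta.n_frames - 1)) < 3 * sigma
        assert abs(endpoint["dy_nm"]) < 3 * sigma

    def test_two_fiducials_match_single_fiducial_estimate(self):
        spec1, locs1, _ = self._scene("linear", n_fiducials=1)
        spec2, locs2, _ = self._scene("linear", n_fiducials=2)
        d1 = estimate_drift(locs1, detect_fiducials(locs1), spec1.meta.n_frames)
        d2 = estimate_drift(locs2, detect_fiducials(locs2), spec2.meta.n_frames)
        resid = (d1[["dx_nm", "dy_nm"]] - d2[["dx_nm", "dy_nm"]]).to_numpy()
        assert np.abs(resid).max() < 3 * locs1["precision_nm"].median()

    def test_no_fiducials_is_an_error(self):
        t = _fiducial_table(10)
        with pytest.raises(ValueError, match="no fiducials"):
            estimate_drift(t, [], 10)

    def test_apply_zero_drift_is_identity_and_negation_inverts(self):
        spec, locs, _ = self._scene("none", n_fiducials=1)
        zero = pd.DataFrame(
            {"frame": np.arange(spec.meta.n_frames), "dx_nm": 0.0, "dy_nm": 0.0}
        )
        same = apply_drift(locs, zero)
        pd.testing.assert_frame_equal(same, locs)
        d = pd.DataFrame(
            {"frame": np.arange(spec.meta.n_frames), "dx_nm": 3.0, "dy_nm": -2.0}
        )
        neg = d.assign(dx_nm=-d["dx_nm"], dy_nm=-d["dy_nm"])
        back = apply_drift(apply_drift(locs, d), neg)
        assert np.allclose(back[["x_nm", "y_nm"]], locs[["x_nm", "y_nm"]])

    def test_apply_drift_preserves_same_frame_distances(self):
        spec, locs, _ = self._scene("linear", n_fiducials=2)
        d = estimate_drift(locs, detect_fiducials(locs), spec.meta.n_frames)
        out = apply_drift(locs, d)
        f0 = locs["frame"] == 0
        before = np.diff(locs.loc[f0, ["x_nm", "y_nm"]].to_numpy(), axis=0)
        after = np.diff(out.loc[f0, ["x_nm", "y_nm"]].to_numpy(), axis=0)
        assert np.allclose(before, after)

    def test_frame_outside_drift_domain_raises(self):
        t = _fiducial_table(10)
        d = pd.DataFrame({"frame": np.arange(5), "dx_nm": 0.0, "dy_nm": 0.0})
        with pytest.raises(ValueError, match="cover"):
            apply_drift(t, d)

    def test_correction_restores_fiducials_to_precision_floor(self):
        spec, locs, truth = self._scene("linear")
        tracks = detect_fiducials(locs)
        drift = estimate_drift(locs, tracks, spec.meta.n_frames)
        corrected = apply_drift(locs, drift)
        sigma = locs["precision_nm"].median()  # per-axis scatter
        for t in tracks:
            raw = locs.iloc[t["member_index"]][["x_nm", "y_nm"]].to_numpy()
            xy = corrected.iloc[t["member_index"]][["x_nm", "y_nm"]].to_numpy()
            rms_axis = np.sqrt(((xy - xy.mean(0)) ** 2).mean(0))
            rms_raw = np.sqrt(((raw - raw.mean(0)) ** 2).mean(0))
            # corrected scatter sits at the localization precision, far
            # below the drift-dominated uncorrected scatter
            assert (rms_axis < 1.1 * sigma).all()
            assert rms_axis.max() < 0.1 * rms_raw.max()

    def test_estimated_drift_tracks_truth_within_spec_band(self):
        spec, locs, truth = self._scene("linear", n_fiducials=3)
        tracks = detect_fiducials(locs)
        drift = estimate_drift(locs, tracks, spec.meta.n_frames)
        est = drift[["dx_nm", "dy_nm"]].to_numpy()
        true = truth.drift[["dx_nm", "dy_nm"]].to_numpy()
        sigma = locs["precision_nm"].median()
        # max |estimated - true| <= 3 sigma / sqrt(n_fiducials) after smoothing
        assert np.abs(est - (true - true[0])).max() <= 3 * sigma / np.sqrt(len(tracks))


class TestRender:
    def test_single_localization_single_pixel(self):
        t = pd.DataFrame(
            {"frame": [0], "x_nm": [100.0], "y_nm": [200.0],
             "precision_nm": [5.0], "signal": [100.0], "background": [0.0]}
        )
        r = render_superres(t, META100, render_px_nm=13.0)
        assert r.sum() == 1 and r.max() == 1

    def test_total_counts_conserved(self, default_scene):
        spec, locs, _ = default_scene
        r = render_superres(locs, spec.meta)
        assert r.sum() == len(locs)

    def test_104nm_fibril_occupies_8_to_9_columns(self):
        xs = np.linspace(1000.0, 1104.0, 50)
        t = pd.DataFrame(
            {"frame": 0, "x_nm": xs, "y_nm": 500.0,
             "precision_nm": 5.0, "signal": 100.0, "background": 0.0}
        )
        r = render_superres(t, META100, render_px_nm=13.0)
        occupied_cols = np.unique(np.nonzero(r)[1])
        assert len(occupied_cols) in (8, 9)

    def test_remove_fiducials_drops_only_members(self, default_scene):
        spec, locs, truth = default_scene
        tracks = detect_fiducials(filter_localizations(locs))
        kept = remove_fiducials(filter_localizations(locs), tracks)
        n_fid = sum(len(t["member_index"]) for t in tracks)
        assert len(kept) == len(filter_localizations(locs)) - n_fid
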