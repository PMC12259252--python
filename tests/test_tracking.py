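"""Detection, linking, eligibility, and random selection."""

import numpy as np
import pandas as pd
import pytest

from mccquant.synthetic import (AcquisitionSpec, FlowFieldSpec,
                                simulate_tracks, render_frames)
from mccquant.tracking import (SelectionSpec, Track, detect_beads,
                               link_detections, eligible_tracks,
                               select_beads, tracks_to_dataframe,
                               dataframe_to_tracks, read_trackmate_csv)
from conftest import separated_grid


def link_accuracy(tracks, truth, match_radius=0.5):
    """Fraction of within-track links that connect the same true bead."""
    correct = total = 0
    for t in tracks:
        for k in range(len(t) - 1):
            ids = []
            for frame, pos in ((t.frames[k], t.xy[k]),
                               (t.frames[k + 1], t.xy[k + 1])):
                d = np.linalg.norm(truth.positions[:, frame] - pos, axis=1)
                ids.append(int(np.argmin(d)) if d.min() < match_radius
                           else -1)
            total += 1
            correct += ids[0] == ids[1] != -1
    return correct / total


class TestDetectBeads:
    def test_single_spot_localized_within_half_pixel(self):
        acq = AcquisitionSpec(seed=0, n_frames=7, n_beads=1, noise_sd=0.0,
                              dropout_prob=0.0, field_width=20.0,
                              field_height=20.0)
        truth = simulate_tracks(FlowFieldSpec(base_speed=0.0,
                                              diffusion_coeff=0.0), acq)
        det = detect_beads(render_frames(truth), pixel_size=acq.pixel_size)
        frame0 = det[det["frame"] == 0]
        assert len(frame0) == 1
        x, y = truth.positions[0, 0]
        assert abs(frame0["x_um"].iloc[0] - x) < acq.pixel_size / 2
        assert abs(frame0["y_um"].iloc[0] - y) < acq.pixel_size / 2

    def test_pure_background_yields_no_detections(self):
        rng = np.random.default_rng(0)
        stack = 100.0 + rng.normal(0, 3.0, (3, 64, 64))
        det = detect_beads(stack, pixel_size=0.33)
        assert len(det) == 0

    def test_recall_precision_on_separated_field(self):
        # well-separated spots (grid spacing >> 4 psf_sigma), default noise
        acq = AcquisitionSpec(seed=13, n_frames=7, dropout_prob=0.0)
        init = separated_grid(40, 10, acq)  # 400 beads, spacing >= 6 um
        truth = simulate_tracks(
            FlowFieldSpec(base_speed=0.0, diffusion_coeff=0.05), acq,
            init_positions=init)
        det = detect_beads(render_frames(truth), pixel_size=acq.pixel_size)
        matched = 0
        d0 = det[det["frame"] == 0][["x_um", "y_um"]].to_numpy()
        for pos in truth.positions[:, 0]:
            if np.min(np.linalg.norm(d0 - pos, axis=1)) < 1.0:
                matched += 1
        recall = matched / truth.n_beads
        fp = sum(np.min(np.linalg.norm(truth.positions[:, 0] - p, axis=1))
                 >= 1.0 for p in d0)
        precision = (len(d0) - fp) / len(d0)
        assert recall >= 0.99
        assert precision >= 0.99

    def test_missing_pixel_size_metadata_is_an_error(self, tmp_path):
        import tifffile
        path = tmp_path / "bare.tif"
        tifffile.imwrite(path, np.zeros((2, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="pixel_size_um"):
            detect_beads(path)


class TestLinkDetections:
    @staticmethod
    def _det_from(positions, frames=None):
        n, t = positions.shape[:2]
        rows = []
        for b in range(n):
            for f in range(t):
                rows.append((f, positions[b, f, 0], positions[b, f, 1], 1.0))
        return pd.DataFrame(rows, columns=["frame", "x_um", "y_um",
                                           "intensity"])

    def test_separated_beads_keep_identity(self):
        pos = np.zeros((2, 10, 2))
        pos[0, :, 0] = np.arange(10) * 1.0
        pos[1, :, 0] = np.arange(10) * 1.0
        pos[1, :, 1] = 50.0  # far from bead 0 at all times
        tracks = link_detections(self._det_from(pos), max_disp=3.0)
        assert len(tracks) == 2
        assert all(len(t) == 10 for t in tracks)

    def test_dropout_splits_track_no_gap_closing(self):
        pos = np.zeros((1, 10, 2))
        pos[0, :, 0] = np.arange(10) * 1.0
        det = self._det_from(pos)
        det = det[det["frame"] != 5].reset_index(drop=True)
        tracks = link_detections(det, max_disp=3.0)
        assert sorted(len(t) for t in tracks) == [4, 5]
        assert {tuple(t.frames) for t in tracks} == {
            tuple(range(5)), tuple(range(6, 10))}

    def test_link_accuracy_on_separated_simulation(self):
        acq = AcquisitionSpec(seed=14, n_frames=10, dropout_prob=0.0,
                              localization_noise_sd=0.05)
        init = separated_grid(40, 10, acq)
        truth = simulate_tracks(
            FlowFieldSpec(base_speed=5.0, diffusion_coeff=0.2,
                          patch_direction_sd=0.0, angular_jitter_sd=0.1),
            acq, init_positions=init)
        tracks = link_detections(truth.detections(), max_disp=3.0)
        assert link_accuracy(tracks, truth) >= 0.999

    def test_partition_conserves_detections(self, small_truth):
        det = small_truth.detections()
        tracks = link_detections(det, max_disp=3.0)
        assert sum(len(t) for t in tracks) == len(det)

    def test_gate_respected_within_tracks(self, small_truth):
        max_disp = 3.0
        tracks = link_detections(small_truth.detections(), max_disp)
        for t in tracks:
            if len(t) > 1:
                steps = np.linalg.norm(np.diff(t.xy, axis=0), axis=1)
                assert np.all(steps <= max_disp)

    def test_empty_input_gives_empty_output(self):
        det = pd.DataFrame(columns=["frame", "x_um", "y_um", "intensity"])
        assert link_detections(det, max_disp=3.0) == []


class TestEligibilityAndSelection:
    def test_seven_frames_eligible_six_not(self):
        # 6 intervals (0.816 s at 136 ms) need 7 frame observations
        t7 = Track(0, np.arange(7), np.zeros((7, 2)))
        t6 = Track(1, np.arange(6), np.zeros((6, 2)))
        assert eligible_tracks([t7, t6]) == [t7]

    def test_eligibility_matches_brute_force_on_dropout_tracks(self):
        truth = simulate_tracks(
            FlowFieldSpec(), AcquisitionSpec(seed=15, n_frames=20,
                                             n_beads=100, dropout_prob=0.2))
        tracks = link_detections(truth.detections(), max_disp=3.0)
        spec = SelectionSpec()
        brute = [t for t in tracks if len(t) >= 7]
        assert eligible_tracks(tracks, spec) == brute

    def test_select_all_when_exactly_enough(self):
        tracks = [Track(i, np.arange(7), np.random.default_rng(i).random((7, 2)))
                  for i in range(10)]
        out = select_beads(tracks, SelectionSpec(seed=0))
        assert [t.track_id for t in out] == list(range(10))

    def test_selection_deterministic_given_seed(self):
        tracks = [Track(i, np.arange(7), np.zeros((7, 2))) for i in range(50)]
        a = select_beads(tracks, SelectionSpec(seed=42))
        b = select_beads(tracks, SelectionSpec(seed=42))
        assert [t.track_id for t in a] == [t.track_id for t in b]

    def test_selection_uniformity_audit(self):
        n_tracks, n_rep = 500, 10_000
        tracks = [Track(i, np.arange(7), np.zeros((7, 2)))
                  for i in range(n_tracks)]
        counts = np.zeros(n_tracks)
        for rep in range(n_rep):
            for t in select_beads(tracks, SelectionSpec(seed=rep)):
                counts[t.track_id] += 1
        p = 10 / n_tracks
        sd = np.sqrt(n_rep * p * (1 - p))
        assert np.all(np.abs(counts - n_rep * p) < 4.5 * sd)
        # distribution-level check: ~99.7% of tracks within 3 sd
        within = np.mean(np.abs(counts - n_rep * p) < 3 * sd)
        assert within > 0.99

    def test_too_few_eligible_reports_both_counts(self):
        tracks = [Track(0, np.arange(7), np.zeros((7, 2)))]
        with pytest.raises(ValueError, match="1 eligible.*n_select=10"):
            select_beads(tracks, SelectionSpec())


class TestTrackIO:
    def test_trackmate_round_trip_lossless(self, tmp_path):
        df = pd.DataFrame({
            "TRACK_ID": [0, 0, 0, 1, 1, 1, 1, 1, 1, 1],
            "FRAME": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9],
            "POSITION_X": np.linspace(0, 9, 10),
            "POSITION_Y": np.linspace(5, 14, 10),
        })
        path = tmp_path / "tm.csv"
        df.to_csv(path, index=False)
        back = read_trackmate_csv(path)
        assert np.array_equal(back["track_id"], df["TRACK_ID"])
        assert np.array_equal(back["frame"], df["FRAME"])
        assert np.allclose(back["x_um"], df["POSITION_X"])
        assert np.allclose(back["y_um"], df["POSITION_Y"])

    def test_trackmate_v7_style_header_rows_skipped(self, tmp_path):
        path = tmp_path / "tm7.csv"
        path.write_text(
            "TRACK_ID,FRAME,POSITION_X,POSITION_Y\n"
            "Track ID,Frame,X,Y\n"
            "Track ID,Frame,(um),(um)\n"
            "0,0,1.5,2.5\n0,1,1.6,2.6\n")
        back = read_trackmate_csv(path)
        assert len(back) == 2
        assert back["x_um"].tolist() == [1.5, 1.6]

    def test_dataframe_round_trip_splits_gaps(self):
        df = pd.DataFrame({"track_id": [0] * 5, "frame": [0, 1, 2, 5, 6],
                           "x_um": np.arange(5.0), "y_um": np.zeros(5)})
        tracks = dataframe_to_tracks(df)
        assert [len(t) for t in tracks] == [3, 2]
        flat = tracks_to_dataframe(tracks)
        assert sorted(flat["frame"]) == [0, 1, 2, 5, 6]
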