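import logging

import numpy as np
import pandas as pd
import pytest

from damscore import pose_io
from damscore.meta import VideoMeta
from damscore.pose_io import (
    BEHAVIORS,
    PoseSeries,
    RawDetections,
    detections_to_table,
    join_dam_pup,
    rasterize_intervals,
    read_annotations,
    read_dam_pose,
    read_detections,
    read_joined,
    write_annotations,
    write_dam_pose,
    write_detections_json,
    write_detections_pickle,
    write_joined,
)
from damscore.schemes import dam_scheme, pup_scheme


def _meta(n_frames=10, video_id="v1", fps=30.0):
    return VideoMeta(video_id=video_id, fps=fps, px_per_mm=2.0, n_frames=n_frames)


def _random_pose(n, seed=0):
    rng = np.random.default_rng(seed)
    coords = np.empty((n, 32, 3))
    coords[:, :, :2] = rng.uniform(0, 1000, size=(n, 32, 2))
    coords[:, :, 2] = rng.uniform(0, 1, size=(n, 32))
    return PoseSeries(meta=_meta(n), scheme=dam_scheme(), coords=coords)


class TestDamPoseCSV:
    def test_round_trip_10_frames(self, tmp_path):
        series = _random_pose(10)
        path = tmp_path / "dam.csv"
        write_dam_pose(series, path)
        back = read_dam_pose(path, series.meta)
        assert back.n_frames == 10
        assert back.coords.shape == (10, 32, 3)  # 96 value columns
        np.testing.assert_array_equal(back.coords, series.coords)

    def test_missing_keypoint_named_in_error(self, tmp_path):
        series = _random_pose(5)
        path = tmp_path / "dam.csv"
        write_dam_pose(series, path)
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        keep = [c for c in df.columns if c[1] != "tail_tip"]
        df[keep].to_csv(tmp_path / "short.csv")
        with pytest.raises(pose_io.SchemaError, match="tail_tip"):
            read_dam_pose(tmp_path / "short.csv", series.meta)

    def test_out_of_range_likelihood_clipped_with_warning(self, tmp_path, caplog):
        series = _random_pose(5)
        path = tmp_path / "dam.csv"
        write_dam_pose(series, path)
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        like_cols = [c for c in df.columns if c[2] == "likelihood"]
        df.loc[3, like_cols[0]] = 1.2
        df.to_csv(path)
        with caplog.at_level(logging.WARNING):
            back = read_dam_pose(path, series.meta)
        assert back.coords[3, 0, 2] == 1.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_non_numeric_cell_reports_frame(self, tmp_path):
        series = _random_pose(5)
        path = tmp_path / "dam.csv"
        write_dam_pose(series, path)
        text = path.read_text().splitlines()
        fields = text[4].split(",")  # frame index 1 (after 3 header rows + frame 0)
        fields[1] = "oops"
        text[4] = ",".join(fields)
        path.write_text("\n".join(text))
        with pytest.raises(pose_io.ParseError, match="frame 1"):
            read_dam_pose(path, series.meta)


def _detections(frame_points, n_frames=None, video_id="v1"):
    """Build RawDetections from {frame: {bodypart: [(x, y, conf), ...]}}."""
    bps = pup_scheme().names
    n = n_frames or (max(frame_points) + 1)
    frames = []
    for t in range(n):
        per = frame_points.get(t, {})
        frames.append({
            bp: np.asarray(per.get(bp, []), dtype=float).reshape(-1, 3)
            for bp in bps
        })
    return RawDetections(meta=_meta(n, video_id=video_id), bodyparts=bps, frames=frames)


class TestDetectionsToTable:
    def test_descending_confidence_fills_slots(self):
        d = _detections({0: {"nose": [(1, 2, 0.9), (3, 4, 0.7), (5, 6, 0.2)]}})
        block = detections_to_table(d, max_pups=8)
        nose = pup_scheme().index("nose")
        assert block.coords[0, 0, nose, 2] == 0.9
        assert block.coords[0, 1, nose, 2] == 0.7
        assert block.coords[0, 2, nose, 2] == 0.2
        assert (block.coords[0, 3:, nose, 2] == 0).all()

    def test_empty_frame_all_slots_zero(self):
        d = _detections({}, n_frames=3)
        block = detections_to_table(d, max_pups=8)
        assert (block.coords == 0).all()

    def test_surplus_detections_keep_highest_confidence(self):
        rng = np.random.default_rng(3)
        pts = [(float(x), float(y), float(c))
               for x, y, c in zip(rng.uniform(0, 100, 10), rng.uniform(0, 100, 10),
                                  rng.uniform(0, 1, 10))]
        d = _detections({0: {"tail_base": pts}})
        block = detections_to_table(d, max_pups=8)
        tb = pup_scheme().index("tail_base")
        kept = sorted(block.coords[0, :, tb, 2], reverse=True)
        expected = sorted((c for _, _, c in pts), reverse=True)[:8]  # brute-force oracle
        assert kept == pytest.approx(expected)

    def test_output_independent_of_input_order(self):
        rng = np.random.default_rng(5)
        pts = [(float(x), float(y), float(c))
               for x, y, c in zip(rng.uniform(0, 100, 6), rng.uniform(0, 100, 6),
                                  rng.choice([0.5, 0.5, 0.9], 6))]
        a = detections_to_table(_detections({0: {"nose": pts}}), max_pups=8)
        b = detections_to_table(_detections({0: {"nose": pts[::-1]}}), max_pups=8)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_bad_max_pups(self):
        with pytest.raises(ValueError):
            detections_to_table(_detections({}, n_frames=1), max_pups=0)


class TestJoin:
    def test_column_count_follows_schema(self):
        dam = _random_pose(100)
        block = detections_to_table(_detections({}, n_frames=100), max_pups=8)
        joined = join_dam_pup(dam, block)
        df = joined.to_dataframe()
        assert df.shape == (100, (32 + 8 * 9) * 3)  # 312 value columns

    def test_length_mismatch_truncates_with_warning(self, caplog):
        dam = _random_pose(100)
        block = detections_to_table(_detections({}, n_frames=98), max_pups=8)
        with caplog.at_level(logging.WARNING):
            joined = join_dam_pup(dam, block)
        assert joined.n_frames == 98
        assert any("truncating" in r.message for r in caplog.records)

    def test_video_id_mismatch_rejected(self):
        dam = _random_pose(10)
        block = detections_to_table(_detections({}, n_frames=10, video_id="other"))
        with pytest.raises(ValueError, match="video_id"):
            join_dam_pup(dam, block)

    def test_joined_round_trip_bit_identical(self, tmp_path, joined):
        path = tmp_path / "joined.csv"
        write_joined(joined, path)
        back = read_joined(path, joined.meta)
        np.testing.assert_array_equal(back.dam, joined.dam)
        np.testing.assert_array_equal(back.pups, joined.pups)


class TestDetectionDialects:
    def test_pickle_and_json_read_identically(self, tmp_path, session):
        d = session.pup_detections
        write_detections_pickle(d, tmp_path / "d_full.pickle")
        write_detections_json(d, tmp_path / "d.json")
        a = read_detections(tmp_path / "d_full.pickle", d.meta)
        b = read_detections(tmp_path / "d.json", d.meta)
        assert a.bodyparts == b.bodyparts == d.bodyparts
        assert a.n_frames == b.n_frames == d.n_frames
        for fa, fb, fd in zip(a.frames, b.frames, d.frames):
            for bp in d.bodyparts:
                np.testing.assert_allclose(fa[bp], fd[bp], atol=1e-12)
                np.testing.assert_allclose(fb[bp], fd[bp], atol=1e-12)

    def test_confidence_clipped_on_read(self, tmp_path, caplog):
        d = _detections({0: {"nose": [(1, 2, 1.4)]}})
        write_detections_json(d, tmp_path / "d.json")
        with caplog.at_level(logging.WARNING):
            back = read_detections(tmp_path / "d.json", d.meta)
        assert back.frames[0]["nose"][0, 2] == 1.0


class TestAnnotations:
    def test_half_open_interval_rasterization(self, tmp_path):
        write_annotations([("licking_grooming", 1.0, 2.0)], tmp_path / "a.csv")
        ann = read_annotations(tmp_path / "a.csv", _meta(n_frames=90))
        pos = ann.frame_labels["licking_grooming"]
        assert pos.sum() == 30
        assert pos[30] and pos[59] and not pos[29] and not pos[60]

    def test_empty_table_all_false(self, tmp_path):
        write_annotations([], tmp_path / "a.csv")
        ann = read_annotations(tmp_path / "a.csv", _meta(n_frames=50))
        assert not ann.frame_labels.any().any()

    def test_unknown_behavior_rejected(self, tmp_path):
        (tmp_path / "a.csv").write_text("Behavior,Start (s),Stop (s)\nretrieval,0,1\n")
        with pytest.raises(ValueError, match="retrieval"):
            read_annotations(tmp_path / "a.csv", _meta())

    def test_stop_before_start_names_row(self, tmp_path):
        (tmp_path / "a.csv").write_text(
            "Behavior,Start (s),Stop (s)\neating,0,1\ndrinking,5,4\n")
        with pytest.raises(ValueError, match="row 1"):
            read_annotations(tmp_path / "a.csv", _meta())

    def test_positive_counts_match_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        fps, n = 30.0, 600
        intervals = []
        for _ in range(25):
            b = BEHAVIORS[rng.integers(len(BEHAVIORS))]
            s = float(rng.uniform(0, 18))
            intervals.append((b, s, s + float(rng.uniform(0.05, 3))))
        labels = rasterize_intervals(intervals, n, fps)
        # brute-force per-frame membership scan
        for b in BEHAVIORS:
            expect = sum(
                any(bb == b and s <= f / fps < e for bb, s, e in intervals)
                for f in range(n)
            )
            assert labels[b].sum() == expect
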