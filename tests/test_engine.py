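import json
import math

import numpy as np
import pytest

from ocutrack.core import BinaryFrame, CRModel, RaySpec, VideoFrame, validate_config
from ocutrack.engine import (
    ArrayImporter,
    Extractor,
    NDJSONLogExtractor,
    detect_crs,
    init_state,
    remove_cr_overlap,
    run,
    track_frame,
)
from ocutrack.synthetic import SceneImporter, blink_scene, drift_scene, plr_scene, static_scene
from ocutrack.walkout import walk_out

from conftest import disk_image


def scene_config(scene, **extra):
    raw = {
        "seed": [int(scene.pupil_cx[0]), int(scene.pupil_cy[0])],
        "threshold": 95,
    }
    raw.update(extra)
    return validate_config(raw)


class TestDetectCRs:
    def test_single_glint_recovered_subpixel(self, scene_preproc):
        scene = static_scene(n_frames=1, glints=(CRModel(cx=40, cy=30, r=3),), noise_sigma=0)
        frame = SceneImporter(scene, 1).__iter__().__next__()
        cfg = scene_config(scene)
        crs, seeds = detect_crs(frame, [(40, 30)], cfg, scene_preproc)
        assert len(crs) == 1
        assert math.hypot(crs[0].cx - 40, crs[0].cy - 30) <= 0.5
        assert abs(crs[0].r - 3) <= 0.7
        assert seeds == [(40, 30)]

    def test_no_glints_yields_empty_list(self, scene_preproc):
        scene = static_scene(n_frames=1, noise_sigma=0)
        frame = next(iter(SceneImporter(scene, 1)))
        crs, seeds = detect_crs(frame, [(40, 30)], scene_config(scene), scene_preproc)
        assert crs == []
        assert seeds == [(40, 30)]  # seed retained for the next frame

    def test_two_glints_matched_to_nearest_seed(self, scene_preproc):
        glints = (CRModel(cx=35, cy=40, r=3), CRModel(cx=60, cy=55, r=2.5))
        scene = static_scene(n_frames=1, glints=glints, noise_sigma=0)
        frame = next(iter(SceneImporter(scene, 1)))
        crs, _ = detect_crs(frame, [(35, 40), (60, 55)], scene_config(scene), scene_preproc)
        assert len(crs) == 2
        assert math.hypot(crs[0].cx - 35, crs[0].cy - 40) <= 0.5
        assert math.hypot(crs[1].cx - 60, crs[1].cy - 55) <= 0.5


class TestRemoveCrOverlap:
    def test_filled_glint_restores_true_edge(self):
        img = disk_image((41, 41), 20, 20, 12)
        img[disk_image((41, 41), 26, 20, 2) == 1] = 0
        east = [i for i, d in enumerate(RaySpec().directions()) if d == (1, 0)][0]
        short = walk_out(BinaryFrame(img), (20, 20), RaySpec())
        assert short.points[short.ray_ids == east][0][0] - 20 < 12
        healed = remove_cr_overlap(BinaryFrame(img), [CRModel(cx=26, cy=20, r=2)])
        full = walk_out(healed, (20, 20), RaySpec())
        assert full.points[full.ray_ids == east][0][0] - 20 == pytest.approx(12.5)

    def test_no_crs_is_identity(self):
        b = BinaryFrame(disk_image((41, 41), 20, 20, 10))
        assert remove_cr_overlap(b, []) is b

    def test_glint_outside_pupil_leaves_contour_unchanged(self):
        img = disk_image((64, 64), 30, 30, 10)
        before = walk_out(BinaryFrame(img), (30, 30), RaySpec())
        healed = remove_cr_overlap(BinaryFrame(img), [CRModel(cx=52, cy=52, r=3)])
        after = walk_out(healed, (30, 30), RaySpec())
        assert np.array_equal(before.points, after.points)


class TestTrackFrame:
    def test_clean_frame_tracks_within_one_pixel(self):
        scene = static_scene(n_frames=1, noise_sigma=0)
        state = init_state(scene_config(scene))
        frame = next(iter(SceneImporter(scene, 1)))
        state, rec = track_frame(state, frame)
        assert rec.method == "walkout" and not rec.blink
        truth = scene.pupil_model(0)
        assert math.hypot(rec.pupil.cx - truth.cx, rec.pupil.cy - truth.cy) < 1.0

    def test_all_dark_frame_is_a_blink(self):
        scene = static_scene(n_frames=1, noise_sigma=0)
        state = init_state(scene_config(scene))
        state, _ = track_frame(state, next(iter(SceneImporter(scene, 1))))
        dark = VideoFrame(pixels=np.zeros((96, 96), dtype=np.uint8), index=1)
        state, rec = track_frame(state, dark)
        assert rec.blink and rec.method == "blink" and rec.pupil is None

    def test_large_jump_recovered_by_hough(self):
        scene = static_scene(n_frames=1, noise_sigma=0, frame_size=(96, 128), center=(40, 47))
        state = init_state(scene_config(scene))
        state, _ = track_frame(state, next(iter(SceneImporter(scene, 1))))
        jumped = static_scene(n_frames=1, noise_sigma=0, frame_size=(96, 128), center=(80, 47))
        state, rec = track_frame(state, VideoFrame(pixels=next(iter(SceneImporter(jumped, 1))).pixels, index=1))
        assert rec.method == "hough_fallback"
        assert math.hypot(rec.pupil.cx - 80, rec.pupil.cy - 47) <= 1.0
        # recovered center becomes the next walk-out seed
        assert state.pupil_seed == (int(round(rec.pupil.cx)), int(round(rec.pupil.cy)))


class FailingExtractor(Extractor):
    def on_record(self, record):
        raise RuntimeError("experiment module crashed")


class CollectingExtractor(Extractor):
    def __init__(self):
        self.records = []
        self.summary = None

    def on_record(self, record):
        self.records.append(record)

    def on_finish(self, summary):
        self.summary = summary


class TestRun:
    def test_plr_video_logs_one_parseable_line_per_frame(self, tmp_path):
        scene = plr_scene(freq_cpm=12, duration_s=5.0, fps=60, noise_sigma=0)
        out = tmp_path / "plr.ndjson"
        summary = run(SceneImporter(scene, 3), [NDJSONLogExtractor(str(out))], scene_config(scene))
        lines = out.read_text().splitlines()
        assert summary["frames"] == scene.n_frames == len(lines) == 300
        parsed = [json.loads(l) for l in lines]
        assert [p["frame"] for p in parsed] == list(range(300))

    def test_zero_frame_importer_yields_empty_summary(self):
        cfg = validate_config({"seed": [20, 20], "threshold": 95})
        summary = run(ArrayImporter([]), [CollectingExtractor()], cfg)
        assert summary == {"frames": 0, "blinks": 0, "fallbacks": 0}

    def test_blink_count_matches_script(self):
        scene = blink_scene(pre_frames=8, blink_frames=5, post_frames=8, noise_sigma=0)
        col = CollectingExtractor()
        summary = run(SceneImporter(scene, 1), [col], scene_config(scene))
        assert summary["blinks"] == 5
        assert [r.blink for r in col.records] == [
            i in scene.blink_frames for i in range(scene.n_frames)
        ]
        assert col.summary == summary

    def test_failing_extractor_does_not_stop_acquisition(self):
        scene = static_scene(n_frames=4, noise_sigma=0)
        col = CollectingExtractor()
        summary = run(SceneImporter(scene, 1), [FailingExtractor(), col], scene_config(scene))
        assert summary["frames"] == 4
        assert len(col.records) == 4

    def test_extractors_receive_independent_record_copies(self):
        scene = static_scene(n_frames=2, noise_sigma=0)

        class Mutator(Extractor):
            def on_record(self, record):
                record.crs.append(CRModel(cx=1, cy=1, r=1))

        col = CollectingExtractor()
        run(SceneImporter(scene, 1), [Mutator(), col], scene_config(scene))
        assert all(r.crs == [] for r in col.records)

    def test_runs_are_byte_identical(self, tmp_path):
        scene = drift_scene(n_frames=40)  # default sensor noise, seeded per frame
        cfg = scene_config(scene)
        paths = []
        for name in ("a.ndjson", "b.ndjson"):
            p = tmp_path / name
            run(SceneImporter(scene, 7), [NDJSONLogExtractor(str(p))], cfg)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_clean_scene_accuracy_median_bounds(self):
        scene = drift_scene(n_frames=300, noise_sigma=0)
        col = CollectingExtractor()
        run(SceneImporter(scene, 1), [col], scene_config(scene))
        errs, aerrs = [], []
        for i, rec in enumerate(col.records):
            truth = scene.pupil_model(i)
            errs.append(math.hypot(rec.pupil.cx - truth.cx, rec.pupil.cy - truth.cy))
            aerrs.append(abs(rec.pupil.area - truth.area) / truth.area)
        assert float(np.median(errs)) < 1.0
        assert float(np.median(aerrs)) < 0.05

    def test_corrupt_frame_skipped_with_run_continuing(self):
        scene = static_scene(n_frames=3, noise_sigma=0)
        frames = list(SceneImporter(scene, 1))
        bad = frames[1]
        object.__setattr__(bad, "pixels", None)  # simulate importer corruption
        col = CollectingExtractor()
        summary = run(frames, [col], scene_config(scene))
        assert summary["frames"] == 2
        assert [r.frame_index for r in col.records] == [0, 2]

    def test_run_requires_an_extractor(self):
        cfg = validate_config({"seed": [20, 20], "threshold": 95})
        with pytest.raises(ValueError):
            run(ArrayImporter([]), [], cfg)
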