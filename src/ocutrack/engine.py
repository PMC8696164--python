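"""Per-frame tracking loop and the Importer/Extractor plug-in surface.

The engine processes frames sequentially: smooth -> glint detection ->
glint-overlap removal -> pupil walk-out seeded at the last accepted fit
center -> occlusion filter -> model fit -> deviation check, escalating to
Hough redetection and blink classification when the primary path fails.
Each frame emits exactly one :class:`~ocutrack.core.TrackingRecord`,
delivered to every registered extractor in order.

Importers are any iterable of :class:`~ocutrack.core.VideoFrame` (optionally
carrying ``fps``/``n_frames`` attributes); extractors implement
``on_record`` plus optional ``on_start``/``on_finish`` hooks.  Extractor
exceptions are logged and swallowed so an experiment module cannot kill
acquisition.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core import (
    BinaryFrame,
    CRModel,
    PupilModel,
    RunConfig,
    PreprocParams,
    TrackingRecord,
    VideoFrame,
)
from .errors import FitError, InsufficientPointsError, SeedError
from .preprocessing import binarize, estimate_params, smooth
from .redetection import classify_blink, deviation_check, hough_redetect
from .shape_fitting import (
    MIN_POINTS_CIRCLE,
    MIN_POINTS_ELLIPSE,
    filter_contour,
    fit_circle,
    fit_ellipse,
)
from .walkout import walk_out

log = logging.getLogger(__name__)

__all__ = [
    "EngineState",
    "ArrayImporter",
    "FrameDirectoryImporter",
    "VideoFileImporter",
    "Extractor",
    "NDJSONLogExtractor",
    "CallbackExtractor",
    "detect_crs",
    "remove_cr_overlap",
    "track_frame",
    "init_state",
    "run",
]


# --------------------------------------------------------------------------
# Importers


class ArrayImporter:
    """Importer over in-memory frames (arrays or VideoFrames)."""

    def __init__(self, frames: Sequence, fps: float = 60.0):
        self._frames = frames
        self.fps = fps
        self.n_frames = len(frames)

    def __iter__(self) -> Iterator[VideoFrame]:
        for i, f in enumerate(self._frames):
            if isinstance(f, VideoFrame):
                yield f
            else:
                yield VideoFrame(pixels=np.asarray(f), index=i, time_s=i / self.fps)


class FrameDirectoryImporter:
    """Importer over a directory of numbered PNG/TIFF frames."""

    PATTERNS = ("*.png", "*.tif", "*.tiff")

    def __init__(self, path: str, fps: float = 60.0):
        self.path = path
        self.fps = fps
        files: list[str] = []
        for pat in self.PATTERNS:
            files.extend(glob.glob(os.path.join(path, pat)))
        if not files:
            raise FileNotFoundError(f"no frame images found under {path!r}")
        self.files = sorted(files)
        self.n_frames = len(self.files)

    def __iter__(self) -> Iterator[VideoFrame]:
        import imageio.v3 as iio

        for i, f in enumerate(self.files):
            px = np.asarray(iio.imread(f))
            if px.ndim == 3:  # collapse RGB(A) to luminance
                px = px[..., :3].mean(axis=2)
            yield VideoFrame(pixels=px, index=i, time_s=i / self.fps)


class VideoFileImporter:
    """Importer over an AVI/MP4 file via imageio (requires an ffmpeg plugin)."""

    def __init__(self, path: str, fps: float | None = None):
        self.path = path
        self.fps = fps
        self.n_frames = None

    def __iter__(self) -> Iterator[VideoFrame]:
        import imageio.v3 as iio

        try:
            frames = iio.imiter(self.path)
        except Exception as exc:  # pragma: no cover - depends on codecs present
            raise RuntimeError(
                f"cannot decode {self.path!r}; install an ffmpeg-backed imageio plugin "
                "or convert the video to a directory of PNG frames"
            ) from exc
        fps = self.fps or 60.0
        for i, px in enumerate(frames):
            px = np.asarray(px)
            if px.ndim == 3:
                px = px[..., :3].mean(axis=2)
            yield VideoFrame(pixels=px, index=i, time_s=i / fps)


# --------------------------------------------------------------------------
# Extractors


class Extractor:
    """Base extractor; subclasses override the hooks they need."""

    def on_start(self, config: RunConfig) -> None:  # noqa: D102
        pass

    def on_record(self, record: TrackingRecord) -> None:  # noqa: D102
        pass

    def on_finish(self, summary: dict) -> None:  # noqa: D102
        pass


class NDJSONLogExtractor(Extractor):
    """Streams each record as one JSON line; the bundled acquisition logger."""

    def __init__(self, path: str):
        self.path = path
        self._fh = None

    def on_start(self, config: RunConfig) -> None:
        self._fh = open(self.path, "w")

    def on_record(self, record: TrackingRecord) -> None:
        assert self._fh is not None, "on_start not called"
        self._fh.write(record.to_json() + "\n")

    def on_finish(self, summary: dict) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None


class CallbackExtractor(Extractor):
    """Adapts a plain callable to the extractor contract (closed-loop hook)."""

    def __init__(self, fn):
        self._fn = fn

    def on_record(self, record: TrackingRecord) -> None:
        self._fn(record)


# --------------------------------------------------------------------------
# Engine state and per-frame operations


@dataclass
class EngineState:
    """Mutable tracking state carried across frames."""

    config: RunConfig
    preproc: PreprocParams | None = None
    last_accepted: PupilModel | None = None
    pupil_seed: tuple[int, int] = (0, 0)
    cr_seeds: list[tuple[int, int]] = field(default_factory=list)
    consecutive_blinks: int = 0
    frames: int = 0
    blinks: int = 0
    fallbacks: int = 0


def init_state(config: RunConfig) -> EngineState:
    return EngineState(
        config=config,
        preproc=config.preproc,
        pupil_seed=tuple(config.pupil_seed),
        cr_seeds=[tuple(s) for s in config.cr_seeds],
    )


MAX_CR_RADIUS_FRAC = 0.2  # glints larger than this fraction of the frame are rejected


def detect_crs(
    frame: VideoFrame,
    seeds: Sequence[tuple[int, int]],
    config: RunConfig,
    preproc: PreprocParams,
) -> tuple[list[CRModel], list[tuple[int, int]]]:
    """Detect corneal reflections by walk-out + circle fit around each seed.

    Glints are small and round, so a reduced 8-ray budget suffices, and the
    glint channel is smoothed by the lighter ``cr_gaussian_sigma`` (heavy
    blur erases a 2-3 px specular spot).  A seed that is off-glint on a
    given frame contributes nothing that frame (not fatal) and keeps its
    previous position.  Returns the detected models and the updated seeds.
    """
    sm = smooth(frame, preproc.cr_gaussian_sigma)
    binary = binarize(sm, preproc, target="cr")
    h, w = binary.shape
    max_r = MAX_CR_RADIUS_FRAC * min(h, w)
    models: list[CRModel] = []
    new_seeds: list[tuple[int, int]] = []
    for seed in seeds:
        seed = (int(round(seed[0])), int(round(seed[1])))
        try:
            cps = walk_out(binary, seed, config.cr_rays)
            if len(cps) < MIN_POINTS_CIRCLE:
                raise InsufficientPointsError("too few glint edge points")
            fit = fit_circle(cps.points)
            if fit.a > max_r:
                raise FitError("glint implausibly large")
        except (SeedError, InsufficientPointsError, FitError):
            new_seeds.append(seed)
            continue
        models.append(CRModel(cx=fit.cx, cy=fit.cy, r=fit.a))
        new_seeds.append((int(round(fit.cx)), int(round(fit.cy))))
    return models, new_seeds


def remove_cr_overlap(binary: BinaryFrame, crs: Sequence[CRModel], margin: float = 1.0) -> BinaryFrame:
    """Fill each glint disk (radius + margin) with 1 in the pupil transform.

    A glint inside the pupil appears as a 0-hole that would stop walk-out
    rays early; filling it lets rays pass through to the true pupil edge.
    Glints entirely outside the pupil become isolated 1-islands that rays
    never reach (they stop at the first 0 before the island).
    """
    if not crs:
        return binary
    px = binary.pixels.copy()
    h, w = px.shape
    yy, xx = np.ogrid[:h, :w]
    for cr in crs:
        rad = cr.r + margin
        px[(xx - cr.cx) ** 2 + (yy - cr.cy) ** 2 <= rad * rad] = 1
    return BinaryFrame(pixels=px)


def _attempt_walkout(
    binary: BinaryFrame, state: EngineState
) -> tuple[PupilModel | None, int, int]:
    """Primary detection path; returns (model | None, n_raw, n_kept)."""
    cfg = state.config
    min_pts = MIN_POINTS_ELLIPSE if cfg.model == "ellipse" else MIN_POINTS_CIRCLE
    try:
        cps = walk_out(binary, state.pupil_seed, cfg.rays)
    except SeedError:
        return None, 0, 0
    n_raw = len(cps)
    if n_raw < MIN_POINTS_CIRCLE:
        return None, n_raw, 0
    try:
        filtered, _ = filter_contour(cps, cfg.filter_mode)
    except InsufficientPointsError:
        return None, n_raw, 0
    kept_pts = filtered.kept_points
    n_kept = len(kept_pts)
    if n_kept < min_pts:
        return None, n_raw, n_kept
    try:
        if cfg.model == "ellipse":
            model = fit_ellipse(kept_pts)
        else:
            model = fit_circle(kept_pts)
    except (FitError, InsufficientPointsError):
        return None, n_raw, n_kept
    return model, n_raw, n_kept


def track_frame(state: EngineState, frame: VideoFrame) -> tuple[EngineState, TrackingRecord]:
    """Process one frame, returning the updated state and its record."""
    cfg = state.config
    if state.preproc is None:
        state.preproc = estimate_params(frame, seed=state.pupil_seed)
    pp = state.preproc

    crs, state.cr_seeds = detect_crs(frame, state.cr_seeds, cfg, pp)
    sm = smooth(frame, pp.gaussian_sigma)
    binary = binarize(sm, pp, target="pupil")
    binary = remove_cr_overlap(binary, crs)

    model, n_raw, n_kept = _attempt_walkout(binary, state)
    excessive = (
        model is not None
        and state.last_accepted is not None
        and deviation_check(state.last_accepted, model, cfg.fallback)
    )
    method = "walkout"
    blink = False
    if model is None or excessive:
        recovered = (
            hough_redetect(binary, state.last_accepted, cfg.fallback)
            if state.last_accepted is not None
            else None
        )
        verdict = classify_blink(recovered)
        blink = verdict["blink"]
        method = verdict["method"]
        model = verdict["pupil"]

    if model is not None:
        state.last_accepted = model
        state.pupil_seed = (int(round(model.cx)), int(round(model.cy)))
        state.consecutive_blinks = 0
        if method == "hough_fallback":
            state.fallbacks += 1
    else:
        state.consecutive_blinks += 1
        state.blinks += 1
    state.frames += 1

    record = TrackingRecord(
        frame_index=frame.index,
        time_s=frame.time_s,
        pupil=model,
        crs=crs,
        blink=blink,
        method=method,
        n_points_raw=n_raw,
        n_points_kept=n_kept,
    )
    return state, record


def run(
    importer: Iterable[VideoFrame],
    extractors: Sequence[Extractor],
    config: RunConfig,
) -> dict:
    """Drive the loop to end-of-stream; returns the run summary.

    Every frame yields exactly one record, passed (as an independent copy)
    to every extractor in registration order.
    """
    if not extractors:
        raise ValueError("at least one extractor is required (the NDJSON logger counts)")
    state = init_state(config)
    for ex in extractors:
        ex.on_start(config)
    for frame in importer:
        try:
            state, record = track_frame(state, frame)
        except Exception:
            # importer-level corruption: skip the frame, keep acquiring
            log.exception("skipping unprocessable frame %r", getattr(frame, "index", None))
            continue
        for ex in extractors:
            try:
                ex.on_record(record.copy())
            except Exception:
                log.exception("extractor %r failed on frame %d", ex, record.frame_index)
    summary = {"frames": state.frames, "blinks": state.blinks, "fallbacks": state.fallbacks}
    for ex in extractors:
        try:
            ex.on_finish(dict(summary))
        except Exception:
            log.exception("extractor %r failed in on_finish", ex)
    return summary
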