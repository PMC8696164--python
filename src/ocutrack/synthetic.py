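"""Ground-truthed synthetic eye-video generator.

Renders dark-pupil IR-style scenes: the pupil is the darkest region, the
iris/background mid-gray, and corneal glints the brightest spots, matching
the imaging geometry the tracker is designed for.  Frames are rasterized
at 4x supersampling and box-downsampled so subpixel ground truth is
meaningful, then perturbed by seeded Gaussian pixel noise (deterministic
per ``(scene, frame, seed)``).

Scenario builders script the kinematics used throughout the test suite:
static and drifting pupils, sine-entrained pupil area (pupillary light
reflex), sawtooth azimuth (optokinetic nystagmus), blink intervals, and
eyelid-like occluding sectors.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .core import CRModel, PupilModel, TrackingRecord, VideoFrame
from .errors import ConfigError
from .oculometrics import sine_brightness

__all__ = [
    "Occluder",
    "EyeScene",
    "Scenario",
    "render_frame",
    "ground_truth_record",
    "SceneImporter",
    "build_scene",
    "make_sequence",
    "static_scene",
    "drift_scene",
    "plr_scene",
    "okr_scene",
    "blink_scene",
    "occluded_scene",
]

SUPERSAMPLE = 4

#: Default rendering intensity levels (8-bit): dark pupil, mid iris
#: background, bright specular glints.
DEFAULT_LEVELS = {"pupil": 40.0, "background": 150.0, "glint": 250.0}

#: Default pixel-noise SD in intensity units; a realistic figure for an
#: IR-illuminated CCD at short exposure.
DEFAULT_NOISE_SIGMA = 2.0


@dataclass(frozen=True)
class Occluder:
    """Angular sector (radians) that covers the pupil beyond a radial cut.

    Emulates eyelid/whisker occlusion: within the sector centered on
    ``center_angle`` with angular ``width``, pupil pixels farther than
    ``cut_frac`` of the local pupil radius render at iris intensity, so
    walk-out rays in that sector terminate early.
    """

    center_angle: float
    width: float
    cut_frac: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.cut_frac < 1):
            raise ValueError("cut_frac must lie in (0, 1)")
        if not (0 < self.width <= 2 * math.pi):
            raise ValueError("width must lie in (0, 2*pi]")


@dataclass
class EyeScene:
    """Per-frame ground-truth description of a synthetic eye video."""

    frame_size: tuple[int, int]  # (H, W)
    fps: float
    pupil_cx: np.ndarray
    pupil_cy: np.ndarray
    pupil_a: np.ndarray
    pupil_b: np.ndarray
    pupil_theta: np.ndarray
    glints: tuple[CRModel, ...] = ()
    occluders: tuple[Occluder, ...] = ()
    blink_frames: frozenset[int] = frozenset()
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    levels: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    azimuth_deg: np.ndarray | None = None  # optional kinematic ground truth

    def __post_init__(self) -> None:
        arrays = [self.pupil_cx, self.pupil_cy, self.pupil_a, self.pupil_b, self.pupil_theta]
        n = {len(np.atleast_1d(a)) for a in arrays}
        if len(n) != 1:
            raise ValueError("per-frame pupil arrays must share one length")
        self.pupil_cx = np.asarray(self.pupil_cx, dtype=float)
        self.pupil_cy = np.asarray(self.pupil_cy, dtype=float)
        self.pupil_a = np.asarray(self.pupil_a, dtype=float)
        self.pupil_b = np.asarray(self.pupil_b, dtype=float)
        self.pupil_theta = np.asarray(self.pupil_theta, dtype=float)
        if not (self.levels["glint"] > self.levels["background"] > self.levels["pupil"]):
            raise ValueError("dark-pupil rendering requires glint > background > pupil intensity")
        h, w = self.frame_size
        margin = 2.0
        for i in range(self.n_frames):
            if i in self.blink_frames:
                continue
            r = max(self.pupil_a[i], self.pupil_b[i])
            if not (
                r + margin <= self.pupil_cx[i] <= w - 1 - r - margin
                and r + margin <= self.pupil_cy[i] <= h - 1 - r - margin
            ):
                raise ValueError(f"pupil leaves the frame (margin {margin} px) at frame {i}")

    @property
    def n_frames(self) -> int:
        return len(self.pupil_cx)

    def pupil_model(self, index: int) -> PupilModel:
        a, b = self.pupil_a[index], self.pupil_b[index]
        theta = self.pupil_theta[index]
        if math.isclose(a, b, rel_tol=1e-12):
            return PupilModel(cx=self.pupil_cx[index], cy=self.pupil_cy[index], a=a, b=a, shape="circle")
        if a < b:
            a, b, theta = b, a, theta + math.pi / 2
        return PupilModel(
            cx=self.pupil_cx[index], cy=self.pupil_cy[index], a=a, b=b, theta=theta, shape="ellipse"
        )


def render_frame(scene: EyeScene, index: int, rng_seed: int = 0) -> VideoFrame:
    """Rasterize one frame (4x supersampled, box-downsampled, seeded noise)."""
    if not (0 <= index < scene.n_frames):
        raise IndexError(f"frame index {index} outside scene of {scene.n_frames} frames")
    h, w = scene.frame_size
    s = SUPERSAMPLE
    lv = scene.levels
    xs = (np.arange(w * s) + 0.5) / s - 0.5
    ys = (np.arange(h * s) + 0.5) / s - 0.5
    xx, yy = np.meshgrid(xs, ys)
    img = np.full((h * s, w * s), lv["background"], dtype=float)

    blink = index in scene.blink_frames
    if not blink:
        cx, cy = scene.pupil_cx[index], scene.pupil_cy[index]
        a, b = scene.pupil_a[index], scene.pupil_b[index]
        th = scene.pupil_theta[index]
        ct, st = math.cos(th), math.sin(th)
        dx, dy = xx - cx, yy - cy
        q = ((dx * ct + dy * st) / a) ** 2 + ((-dx * st + dy * ct) / b) ** 2
        pupil_mask = q <= 1.0
        img[pupil_mask] = lv["pupil"]
        for occ in scene.occluders:
            ang = np.arctan2(dy, dx)
            diff = np.angle(np.exp(1j * (ang - occ.center_angle)))
            sector = np.abs(diff) <= occ.width / 2.0
            img[pupil_mask & sector & (q > occ.cut_frac**2)] = lv["background"]
        for g in scene.glints:
            img[(xx - g.cx) ** 2 + (yy - g.cy) ** 2 <= g.r**2] = lv["glint"]

    img = img.reshape(h, s, w, s).mean(axis=(1, 3))
    if scene.noise_sigma > 0:
        rng = np.random.default_rng([int(rng_seed), int(index)])
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return VideoFrame(pixels=img, index=index, time_s=index / scene.fps)


def ground_truth_record(scene: EyeScene, index: int) -> dict:
    """Per-frame ground truth in the tracking-record schema plus truth flags."""
    blink = index in scene.blink_frames
    pupil = None if blink else scene.pupil_model(index)
    rec = TrackingRecord(
        frame_index=index,
        time_s=index / scene.fps,
        pupil=pupil,
        crs=[] if blink else list(scene.glints),
        blink=blink,
        method="blink" if blink else "walkout",
    ).to_dict()
    rec["truth"] = True
    if scene.azimuth_deg is not None:
        rec["azimuth_deg"] = float(scene.azimuth_deg[index])
    return rec


class SceneImporter:
    """Engine importer that renders a scene on the fly (no disk round-trip)."""

    def __init__(self, scene: EyeScene, rng_seed: int = 0):
        self.scene = scene
        self.rng_seed = rng_seed
        self.fps = scene.fps
        self.n_frames = scene.n_frames

    def __iter__(self) -> Iterator[VideoFrame]:
        for i in range(self.scene.n_frames):
            yield render_frame(self.scene, i, self.rng_seed)


# --------------------------------------------------------------------------
# Scenario builders


def _const(n: int, v: float) -> np.ndarray:
    return np.full(n, float(v))


def static_scene(
    n_frames: int = 10,
    frame_size: tuple[int, int] = (96, 96),
    fps: float = 60.0,
    radius: float = 12.0,
    center: tuple[float, float] | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    glints: tuple[CRModel, ...] = (),
    occluders: tuple[Occluder, ...] = (),
) -> EyeScene:
    h, w = frame_size
    cx, cy = center if center is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
    return EyeScene(
        frame_size=frame_size,
        fps=fps,
        pupil_cx=_const(n_frames, cx),
        pupil_cy=_const(n_frames, cy),
        pupil_a=_const(n_frames, radius),
        pupil_b=_const(n_frames, radius),
        pupil_theta=_const(n_frames, 0.0),
        glints=glints,
        occluders=occluders,
        noise_sigma=noise_sigma,
    )


def drift_scene(
    n_frames: int = 120,
    frame_size: tuple[int, int] = (96, 96),
    fps: float = 60.0,
    radius: float = 12.0,
    velocity_px: tuple[float, float] = (0.15, 0.05),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> EyeScene:
    """Pupil translating at a constant sub-policy velocity (px/frame)."""
    h, w = frame_size
    t = np.arange(n_frames, dtype=float)
    span_x = velocity_px[0] * (n_frames - 1)
    span_y = velocity_px[1] * (n_frames - 1)
    x0 = (w - 1) / 2.0 - span_x / 2.0
    y0 = (h - 1) / 2.0 - span_y / 2.0
    return EyeScene(
        frame_size=frame_size,
        fps=fps,
        pupil_cx=x0 + velocity_px[0] * t,
        pupil_cy=y0 + velocity_px[1] * t,
        pupil_a=_const(n_frames, radius),
        pupil_b=_const(n_frames, radius),
        pupil_theta=_const(n_frames, 0.0),
        noise_sigma=noise_sigma,
    )


def plr_scene(
    freq_cpm: float = 6.0,
    duration_s: float = 30.0,
    fps: float = 60.0,
    frame_size: tuple[int, int] = (96, 96),
    base_radius: float = 12.0,
    gain: float = 0.3,
    latency_s: float = 0.5,
    asymmetry: float = 1.0,
    waveform: str = "sine",
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> EyeScene:
    """Pupil area entrained to a sine brightness drive (inverse proportion).

    ``waveform="sine"`` gives symmetric constriction/dilation; with
    ``"triangle"`` each period falls linearly for a fraction
    ``1/(1+asymmetry)`` of the period and rises for the rest, so the
    constriction-to-dilation speed ratio equals ``asymmetry`` exactly.
    """
    if asymmetry <= 0:
        raise ConfigError("asymmetry (v_c/v_d) must be positive")
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    area0 = math.pi * base_radius**2
    a_hi, a_lo = area0 * (1 + gain), area0 * (1 - gain)
    period = 60.0 / freq_cpm
    tau = (t - latency_s) % period
    if waveform == "sine":
        drive = 2.0 * sine_brightness(t - latency_s, freq_cpm) - 1.0  # [-1, 1]
        area = area0 * (1.0 - gain * drive)
    elif waveform == "triangle":
        t_c = period / (1.0 + asymmetry)
        area = np.where(
            tau < t_c,
            a_hi - (a_hi - a_lo) * tau / t_c,
            a_lo + (a_hi - a_lo) * (tau - t_c) / (period - t_c),
        )
    else:
        raise ConfigError("waveform must be 'sine' or 'triangle'")
    r = np.sqrt(area / math.pi)
    h, w = frame_size
    return EyeScene(
        frame_size=frame_size,
        fps=fps,
        pupil_cx=_const(n, (w - 1) / 2.0),
        pupil_cy=_const(n, (h - 1) / 2.0),
        pupil_a=r,
        pupil_b=r,
        pupil_theta=_const(n, 0.0),
        noise_sigma=noise_sigma,
    )


def okr_scene(
    duration_s: float = 60.0,
    fps: float = 60.0,
    frame_size: tuple[int, int] = (96, 128),
    radius: float = 10.0,
    slow_speed_deg_s: float = 5.0,
    n_fast: int = 10,
    fast_duration_s: float = 0.15,
    deg_per_px: float = 1.0,
    reflex_intact: bool = True,
    drift_time_s: float = 3.0,
    rng_seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> EyeScene:
    """Sawtooth azimuth: slow tracking at the grating speed, fast resets.

    ``reflex_intact=False`` replaces the sawtooth by a band-limited random
    walk with the same azimuth variance — the phenotype of a failing
    optokinetic reflex: the eye meanders slowly (correlation time
    ``drift_time_s``) but never locks onto the grating and never produces
    resetting fast phases.  The two scenarios thus differ only in
    trajectory structure, not in positional spread.
    """
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    cycle = duration_s / n_fast
    slow_dur = cycle - fast_duration_s
    if slow_dur <= 0:
        raise ConfigError("fast_duration_s must be shorter than one sawtooth cycle")
    amp = slow_speed_deg_s * slow_dur  # degrees swept per slow phase
    tau = t % cycle
    az = np.where(
        tau < slow_dur,
        -amp / 2.0 + slow_speed_deg_s * tau,
        amp / 2.0 - amp * (tau - slow_dur) / fast_duration_s,
    )
    if not reflex_intact:
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng([int(rng_seed), 0x0FA57])
        walk = np.cumsum(rng.normal(0.0, 1.0, size=n))
        walk = gaussian_filter1d(walk, sigma=drift_time_s * fps, mode="nearest")
        walk -= walk.mean()
        target_sd = float(np.std(az))
        az = walk * (target_sd / max(np.std(walk), 1e-12))
    h, w = frame_size
    cx = (w - 1) / 2.0 + az / deg_per_px
    return EyeScene(
        frame_size=frame_size,
        fps=fps,
        pupil_cx=cx,
        pupil_cy=_const(n, (h - 1) / 2.0),
        pupil_a=_const(n, radius),
        pupil_b=_const(n, radius),
        pupil_theta=_const(n, 0.0),
        noise_sigma=noise_sigma,
        azimuth_deg=az,
    )


def blink_scene(
    pre_frames: int = 10,
    blink_frames: int = 10,
    post_frames: int = 10,
    shift_px: float = 3.0,
    frame_size: tuple[int, int] = (96, 96),
    fps: float = 60.0,
    radius: float = 12.0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> EyeScene:
    """Open eye, a full-closure blink interval, then the eye reopens shifted."""
    n = pre_frames + blink_frames + post_frames
    h, w = frame_size
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
    cx = np.full(n, cx0)
    cx[pre_frames + blink_frames :] = cx0 + shift_px
    return EyeScene(
        frame_size=frame_size,
        fps=fps,
        pupil_cx=cx,
        pupil_cy=_const(n, cy0),
        pupil_a=_const(n, radius),
        pupil_b=_const(n, radius),
        pupil_theta=_const(n, 0.0),
        blink_frames=frozenset(range(pre_frames, pre_frames + blink_frames)),
        noise_sigma=noise_sigma,
    )


def occluded_scene(
    n_frames: int = 10,
    frame_size: tuple[int, int] = (96, 96),
    fps: float = 60.0,
    a: float = 12.0,
    b: float = 12.0,
    theta: float = 0.0,
    occluder: Occluder = Occluder(center_angle=-math.pi / 2, width=math.pi / 2, cut_frac=0.6),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> EyeScene:
    """Static pupil with an eyelid-like occluding sector."""
    h, w = frame_size
    return EyeScene(
        frame_size=frame_size,
        fps=fps,
        pupil_cx=_const(n_frames, (w - 1) / 2.0),
        pupil_cy=_const(n_frames, (h - 1) / 2.0),
        pupil_a=_const(n_frames, max(a, b)),
        pupil_b=_const(n_frames, min(a, b)),
        pupil_theta=_const(n_frames, theta),
        occluders=(occluder,),
        noise_sigma=noise_sigma,
    )


# --------------------------------------------------------------------------
# Named scenarios and file output


@dataclass(frozen=True)
class Scenario:
    """Named scenario: builder kind plus keyword parameters."""

    kind: str
    params: dict = field(default_factory=dict)


_BUILDERS = {
    "static": static_scene,
    "drift": drift_scene,
    "plr_sine": plr_scene,
    "okr_sawtooth": okr_scene,
    "blink_script": blink_scene,
    "occluded": occluded_scene,
}


def build_scene(scenario: Scenario, seed: int = 0) -> EyeScene:
    if scenario.kind not in _BUILDERS:
        raise ConfigError(f"unknown scenario kind {scenario.kind!r}; known: {sorted(_BUILDERS)}")
    params = dict(scenario.params)
    if scenario.kind == "okr_sawtooth":
        params.setdefault("rng_seed", seed)
    return _BUILDERS[scenario.kind](**params)


def make_sequence(scenario: Scenario, seed: int, out_dir: str) -> tuple[str, str]:
    """Render a scenario to PNG frames plus ground-truth NDJSON.

    Writes ``frame_000000.png`` ... under ``out_dir`` along with
    ``truth.ndjson`` (tracking-record schema with ``"truth": true``) and
    ``scenario.json``.  Returns ``(out_dir, truth_path)``.
    """
    import imageio.v3 as iio

    scene = build_scene(scenario, seed)
    os.makedirs(out_dir, exist_ok=True)
    for i in range(scene.n_frames):
        frame = render_frame(scene, i, seed)
        iio.imwrite(os.path.join(out_dir, f"frame_{i:06d}.png"), frame.pixels)
    truth_path = os.path.join(out_dir, "truth.ndjson")
    with open(truth_path, "w") as fh:
        for i in range(scene.n_frames):
            fh.write(json.dumps(ground_truth_record(scene, i), separators=(",", ":")) + "\n")
    with open(os.path.join(out_dir, "scenario.json"), "w") as fh:
        json.dump({"kind": scenario.kind, "params": scenario.params, "seed": seed}, fh, indent=2)
    return out_dir, truth_path
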