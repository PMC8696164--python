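"""Shared data model for the video-oculography pipeline.

Coordinate convention used throughout the package: ``x`` is the column
index, ``y`` the row index, origin at the top-left corner, 0-based, with
pixel centers at integer coordinates.  Angles are measured
counter-clockwise from the +x axis in image coordinates and normalized to
``[0, pi)`` (an ellipse is symmetric under a half-turn of its major axis).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ConfigError

__all__ = [
    "VideoFrame",
    "BinaryFrame",
    "PreprocParams",
    "RaySpec",
    "ContourPointSet",
    "PupilModel",
    "CRModel",
    "TrackingRecord",
    "FallbackPolicy",
    "RunConfig",
    "validate_config",
    "write_ndjson",
    "read_ndjson",
]

MIN_FRAME_SIDE = 16

#: Default diagonal step pairs.  Together with the four cardinal axes and
#: closed under sign flips and axis swaps these yield 32 near-uniformly
#: spread ray directions (the default contour budget).
DEFAULT_DIAGONAL_STEPS: tuple[tuple[int, int], ...] = (
    (1, 1),
    (1, 2),
    (2, 1),
    (1, 3),
    (3, 1),
    (2, 3),
    (3, 2),
)

#: Step pairs whose signed/swap closure plus cardinals gives 64 directions,
#: for scenes that benefit from a denser contour.
DENSE_DIAGONAL_STEPS: tuple[tuple[int, int], ...] = (
    (1, 1),
    (1, 2),
    (1, 3),
    (2, 3),
    (1, 4),
    (3, 4),
    (1, 5),
    (2, 5),
)


@dataclass(frozen=True)
class VideoFrame:
    """One grayscale frame flowing through the tracking loop."""

    pixels: np.ndarray
    index: int = 0
    time_s: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("frame must be a 2-D intensity array")
        h, w = px.shape
        if h < MIN_FRAME_SIDE or w < MIN_FRAME_SIDE:
            raise ValueError(f"frame must be at least {MIN_FRAME_SIDE}x{MIN_FRAME_SIDE}, got {px.shape}")
        if px.size and (float(px.min()) < 0 or float(px.max()) > 255):
            raise ValueError("intensities must lie in [0, 255]")
        if self.index < 0:
            raise ValueError("frame index must be nonnegative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryFrame:
    """Thresholded frame; target-blob (pupil or glint) pixels equal 1."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("binary frame must be 2-D")
        if px.dtype != np.uint8:
            px = px.astype(np.uint8)
        if px.size and not np.isin(px, (0, 1)).all():
            raise ValueError("binary frame must contain only 0/1")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PreprocParams:
    """Thresholding/smoothing parameters for one run.

    ``invert=True`` means the target is darker than its surround in the raw
    frame (dark-pupil imaging) so intensities at or below the threshold map
    to 1.  Corneal reflections are bright, hence carry their own
    ``(cr_threshold, cr_invert)`` pair, normally ``invert=False``; they are
    also only a few pixels across, so their channel uses a lighter blur
    (``cr_gaussian_sigma``) than the pupil channel.
    """

    threshold: float
    invert: bool = True
    gaussian_sigma: float = 2.0
    cr_threshold: float = 200.0
    cr_invert: bool = False
    cr_gaussian_sigma: float = 1.0

    def __post_init__(self) -> None:
        for name, t in (("threshold", self.threshold), ("cr_threshold", self.cr_threshold)):
            if not (0 <= t <= 255):
                raise ConfigError(f"{name} must lie in [0, 255], got {t}")
        if self.gaussian_sigma < 0 or self.cr_gaussian_sigma < 0:
            raise ConfigError("gaussian sigmas must be >= 0")


@dataclass(frozen=True)
class RaySpec:
    """Direction budget for the walk-out.

    The direction set is the four cardinal axes (optional) plus the signed
    and axis-swapped closure of ``diagonal_steps``; the closure must
    produce exactly ``n_points`` distinct directions.
    """

    n_points: int = 32
    diagonal_steps: tuple[tuple[int, int], ...] = DEFAULT_DIAGONAL_STEPS
    include_cardinals: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 8 or self.n_points % 2:
            raise ConfigError("n_points must be even and >= 8")
        steps = tuple((int(m), int(n)) for m, n in self.diagonal_steps)
        for m, n in steps:
            if m == 0 or n == 0:
                raise ConfigError(f"diagonal step {(m, n)} must have nonzero components")
            if math.gcd(abs(m), abs(n)) != 1:
                raise ConfigError(f"diagonal step {(m, n)} must be coprime")
        object.__setattr__(self, "diagonal_steps", steps)
        if len(self.directions()) != self.n_points:
            raise ConfigError(
                f"diagonal_steps yield {len(self.directions())} distinct directions, "
                f"but n_points={self.n_points}"
            )

    def directions(self) -> list[tuple[int, int]]:
        """Ordered, deduplicated (dx, dy) step set."""
        out: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()

        def add(d: tuple[int, int]) -> None:
            if d not in seen:
                seen.add(d)
                out.append(d)

        if self.include_cardinals:
            for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                add(d)
        for m, n in self.diagonal_steps:
            for a, b in ((m, n), (n, m)):
                for sa in (1, -1):
                    for sb in (1, -1):
                        add((sa * a, sb * b))
        return out


@dataclass
class ContourPointSet:
    """Walk-out edge hits with per-point ray provenance and filter verdicts."""

    points: np.ndarray  # (N, 2) float, (x, y)
    ray_ids: np.ndarray  # (N,) int
    kept: np.ndarray  # (N,) bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.ray_ids = np.asarray(self.ray_ids, dtype=int).reshape(-1)
        self.kept = np.asarray(self.kept, dtype=bool).reshape(-1)
        if not (len(self.points) == len(self.ray_ids) == len(self.kept)):
            raise ValueError("points, ray_ids and kept must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def kept_points(self) -> np.ndarray:
        return self.points[self.kept]


def _normalize_angle(theta: float) -> float:
    t = float(theta) % math.pi
    return 0.0 if abs(t - math.pi) < 1e-12 else t


@dataclass(frozen=True)
class PupilModel:
    """Fitted pupil: general ellipse, or circle represented with a == b."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0
    shape: str = "ellipse"

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "circle"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (self.a >= self.b > 0):
            raise ValueError(f"semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")
        theta = _normalize_angle(self.theta)
        if self.shape == "circle":
            if not math.isclose(self.a, self.b, rel_tol=1e-9):
                raise ValueError("circle model requires a == b")
            theta = 0.0
        object.__setattr__(self, "theta", theta)

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)

    @property
    def area(self) -> float:
        """Ellipse area pi*a*b in squared pixels."""
        return math.pi * self.a * self.b

    def to_dict(self) -> dict:
        return {
            "cx": self.cx,
            "cy": self.cy,
            "a": self.a,
            "b": self.b,
            "theta": self.theta,
            "area": self.area,
        }

    @classmethod
    def from_dict(cls, d: dict, shape: str = "ellipse") -> "PupilModel":
        if math.isclose(d["a"], d["b"], rel_tol=1e-9):
            shape = "circle"
        return cls(cx=d["cx"], cy=d["cy"], a=d["a"], b=d["b"], theta=d.get("theta", 0.0), shape=shape)


@dataclass(frozen=True)
class CRModel:
    """Corneal-reflection glint modelled as a circle."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("glint radius must be positive")

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "r": self.r}

    @classmethod
    def from_dict(cls, d: dict) -> "CRModel":
        return cls(cx=d["cx"], cy=d["cy"], r=d["r"])


VALID_METHODS = ("walkout", "hough_fallback", "blink")


@dataclass
class TrackingRecord:
    """Per-frame JSON-serializable tracking result."""

    frame_index: int
    time_s: float | None
    pupil: PupilModel | None
    crs: list[CRModel]
    blink: bool
    method: str
    n_points_raw: int = 0
    n_points_kept: int = 0

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(f"method must be one of {VALID_METHODS}")
        if self.blink and (self.pupil is not None or self.method != "blink"):
            raise ValueError("blink records carry no pupil and method 'blink'")

    def copy(self) -> "TrackingRecord":
        return replace(self, crs=list(self.crs))

    def to_dict(self) -> dict:
        return {
            "frame": self.frame_index,
            "time_s": self.time_s,
            "blink": self.blink,
            "method": self.method,
            "pupil": None if self.pupil is None else self.pupil.to_dict(),
            "crs": [cr.to_dict() for cr in self.crs],
            "n_points_raw": self.n_points_raw,
            "n_points_kept": self.n_points_kept,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict) -> "TrackingRecord":
        pupil = None if d.get("pupil") is None else PupilModel.from_dict(d["pupil"])
        return cls(
            frame_index=d["frame"],
            time_s=d.get("time_s"),
            pupil=pupil,
            crs=[CRModel.from_dict(c) for c in d.get("crs", [])],
            blink=d["blink"],
            method=d["method"],
            n_points_raw=d.get("n_points_raw", 0),
            n_points_kept=d.get("n_points_kept", 0),
        )

    @classmethod
    def from_json(cls, line: str) -> "TrackingRecord":
        return cls.from_dict(json.loads(line))


def write_ndjson(records: Iterable[TrackingRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_ndjson(path) -> Iterator[TrackingRecord]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield TrackingRecord.from_json(line)


@dataclass(frozen=True)
class FallbackPolicy:
    """When to distrust the walk-out and how to score Hough candidates.

    ``center_jump_frac`` bounds the per-frame center jump as a fraction of
    the previous minor-axis *length* (2b); the default 0.25 gives a 2 px
    limit for an 8 px minor axis.  Area may change at most
    ``max_area_ratio_jump``-fold between frames (inclusive).  The Hough
    search spans radii within ``hough_radius_span`` of the previous radius,
    and a candidate is accepted only if its combined score reaches
    ``min_score``.
    """

    center_jump_frac: float = 0.25
    max_area_ratio_jump: float = 1.5
    hough_radius_span: float = 0.4
    min_score: float = 0.25
    min_accumulator: float = 0.2

    def __post_init__(self) -> None:
        if self.center_jump_frac <= 0 or self.max_area_ratio_jump <= 1:
            raise ConfigError("jump bounds must be positive (area ratio > 1)")
        if not (0 < self.hough_radius_span <= 1):
            raise ConfigError("hough_radius_span must lie in (0, 1]")
        if not (0 <= self.min_score <= 1):
            raise ConfigError("min_score must lie in [0, 1]")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for one tracking run."""

    pupil_seed: tuple[int, int]
    cr_seeds: tuple[tuple[int, int], ...] = ()
    model: str = "circle"
    preproc: PreprocParams | None = None  # None => estimate from first frame
    rays: RaySpec = field(default_factory=RaySpec)
    cr_rays: RaySpec = field(default_factory=lambda: RaySpec(n_points=8, diagonal_steps=((1, 1),)))
    fallback: FallbackPolicy = field(default_factory=FallbackPolicy)
    filter_mode: str = "two_sided"
    fps: float = 60.0

    def __post_init__(self) -> None:
        if self.model not in ("circle", "ellipse"):
            raise ConfigError(f"model must be 'circle' or 'ellipse', got {self.model!r}")
        if self.filter_mode not in ("two_sided", "one_sided"):
            raise ConfigError("filter_mode must be 'two_sided' or 'one_sided'")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")


_KNOWN_KEYS = {
    "seed",
    "cr_seeds",
    "model",
    "threshold",
    "invert",
    "gaussian_sigma",
    "cr_threshold",
    "cr_invert",
    "cr_gaussian_sigma",
    "n_points",
    "diagonal_steps",
    "include_cardinals",
    "filter_mode",
    "center_jump_frac",
    "max_area_ratio_jump",
    "hough_radius_span",
    "min_score",
    "fps",
}


def _as_xy(value, what: str) -> tuple[int, int]:
    try:
        x, y = value
        return (int(x), int(y))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{what} must be an (x, y) pair, got {value!r}") from exc


def validate_config(raw: dict) -> RunConfig:
    """Build a fully defaulted :class:`RunConfig` from a flat mapping.

    Unknown keys are rejected so configuration typos fail loudly.
    """
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("threshold", "cr_threshold"):
        if key in raw and not (0 <= float(raw[key]) <= 255):
            raise ConfigError(f"{key} must lie in [0, 255], got {raw[key]}")
    if "seed" not in raw or raw["seed"] is None:
        raise ConfigError("pupil seed required")
    seed = _as_xy(raw["seed"], "seed")
    cr_seeds = tuple(_as_xy(s, "cr_seed") for s in raw.get("cr_seeds", ()))

    preproc = None
    if "threshold" in raw:
        preproc = PreprocParams(
            threshold=float(raw["threshold"]),
            invert=bool(raw.get("invert", True)),
            gaussian_sigma=float(raw.get("gaussian_sigma", 2.0)),
            cr_threshold=float(raw.get("cr_threshold", 200.0)),
            cr_invert=bool(raw.get("cr_invert", False)),
            cr_gaussian_sigma=float(raw.get("cr_gaussian_sigma", 1.0)),
        )
    elif any(k in raw for k in ("cr_threshold", "invert", "cr_invert", "gaussian_sigma")):
        raise ConfigError("preprocessing overrides require an explicit 'threshold'")

    rays_kwargs: dict = {}
    if "n_points" in raw:
        rays_kwargs["n_points"] = int(raw["n_points"])
    if "diagonal_steps" in raw:
        rays_kwargs["diagonal_steps"] = tuple(tuple(p) for p in raw["diagonal_steps"])
    if "include_cardinals" in raw:
        rays_kwargs["include_cardinals"] = bool(raw["include_cardinals"])
    rays = RaySpec(**rays_kwargs)

    fb_kwargs = {
        k: float(raw[k])
        for k in ("center_jump_frac", "max_area_ratio_jump", "hough_radius_span", "min_score")
        if k in raw
    }
    return RunConfig(
        pupil_seed=seed,
        cr_seeds=cr_seeds,
        model=str(raw.get("model", "circle")),
        preproc=preproc,
        rays=rays,
        fallback=FallbackPolicy(**fb_kwargs),
        filter_mode=str(raw.get("filter_mode", "two_sided")),
        fps=float(raw.get("fps", 60.0)),
    )
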