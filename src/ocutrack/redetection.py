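"""Frame-to-frame deviation checks, Hough recovery, and blink classification.

When the walk-out result jumps implausibly between frames (typically a
blink), the tracker falls back on a circular Hough transform restricted to
radii near the last accepted pupil.  Candidate circles are scored by the
product of three [0, 1] terms — proximity to the prior center, similarity
of area, and the fraction of foreground pixels inside the candidate — so
any vanishing term vetoes the candidate.  If no candidate reaches the
acceptance score, the frame is classified as a blink.

A circle accumulator (rather than a 5-parameter ellipse Hough) is used
deliberately: the fallback's job is re-seeding the walk-out, which is
re-run from the recovered center anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.transform import hough_circle, hough_circle_peaks

from .core import BinaryFrame, FallbackPolicy, PupilModel

__all__ = [
    "CandidateScore",
    "deviation_check",
    "position_term",
    "size_term",
    "fill_term",
    "score_candidate",
    "hough_redetect",
    "classify_blink",
]


def deviation_check(prev: PupilModel, curr: PupilModel, policy: FallbackPolicy) -> bool:
    """True when the new fit deviates excessively from the previous one.

    Excessive means the center jumped more than ``center_jump_frac`` times
    the previous minor-axis length (2b), or the area changed by more than
    ``max_area_ratio_jump``-fold.  Bounds are inclusive: a jump exactly at
    the limit is accepted.
    """
    jump = math.hypot(curr.cx - prev.cx, curr.cy - prev.cy)
    limit = policy.center_jump_frac * (2.0 * prev.b)
    if jump > limit:
        return True
    ratio = curr.area / prev.area
    return ratio > policy.max_area_ratio_jump or ratio < 1.0 / policy.max_area_ratio_jump


@dataclass(frozen=True)
class CandidateScore:
    """Three-term score of one Hough candidate; total is their product."""

    position_term: float
    size_term: float
    fill_term: float

    @property
    def total(self) -> float:
        return self.position_term * self.size_term * self.fill_term


def position_term(dist: float, scale: float) -> float:
    """Gaussian decay with distance from the prior center; 1 at zero."""
    return float(math.exp(-((dist / scale) ** 2)))


def size_term(area: float, prior_area: float) -> float:
    """Exponential decay with the absolute log area ratio; 1 at equality."""
    return float(math.exp(-abs(math.log(area / prior_area))))


def fill_term(binary: BinaryFrame, cx: float, cy: float, r: float) -> float:
    """Fraction of candidate-interior pixels that are foreground."""
    h, w = binary.shape
    yy, xx = np.ogrid[:h, :w]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    n = int(inside.sum())
    if n == 0:
        return 0.0
    return float(binary.pixels[inside].mean())


def score_candidate(
    binary: BinaryFrame, prior: PupilModel, cx: float, cy: float, r: float
) -> CandidateScore:
    # The fallback searches the whole frame, so the position term decays on
    # the scale of the frame diagonal: it ranks candidates by proximity
    # without vetoing a lone legitimate re-acquisition far from the prior.
    h, w = binary.shape
    scale = 0.25 * math.hypot(h, w)
    dist = math.hypot(cx - prior.cx, cy - prior.cy)
    return CandidateScore(
        position_term=position_term(dist, scale=scale),
        size_term=size_term(math.pi * r * r, prior.area),
        fill_term=fill_term(binary, cx, cy, r),
    )


def hough_redetect(
    binary: BinaryFrame, prior: PupilModel, policy: FallbackPolicy | None = None
) -> PupilModel | None:
    """Search for the pupil near its last accepted model via circle Hough.

    The accumulator spans radii within ``hough_radius_span`` of the
    prior's mean radius.  Returns the best-scoring candidate at or above
    ``min_score``, or ``None`` (the blink signal) when nothing qualifies.
    """
    policy = policy or FallbackPolicy()
    prior_r = math.sqrt(prior.a * prior.b)
    r_lo = max(2, int(math.floor(prior_r * (1.0 - policy.hough_radius_span))))
    r_hi = max(r_lo + 1, int(math.ceil(prior_r * (1.0 + policy.hough_radius_span))))
    radii = np.arange(r_lo, r_hi + 1)

    fg = binary.pixels.astype(bool)
    # No foreground, or foreground blanketing the frame (an all-dark frame
    # thresholds to all-1): either way there is no pupil/background edge.
    if not fg.any() or fg.mean() > 0.5:
        return None
    edges = fg & ~binary_erosion(fg)
    if not edges.any():
        return None
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rs = hough_circle_peaks(accum, radii, total_num_peaks=8)

    best: tuple[float, PupilModel] | None = None
    for acc, cx, cy, r in zip(accums, cxs, cys, rs):
        if acc < policy.min_accumulator:
            continue
        score = score_candidate(binary, prior, float(cx), float(cy), float(r))
        if score.total >= policy.min_score and (best is None or score.total > best[0]):
            best = (
                score.total,
                PupilModel(cx=float(cx), cy=float(cy), a=float(r), b=float(r), shape="circle"),
            )
    return None if best is None else best[1]


def classify_blink(redetect_result: PupilModel | None) -> dict:
    """Map a redetection outcome onto record fields.

    ``None`` marks a blink; a recovered model marks a fallback frame whose
    center becomes the next frame's walk-out seed (handled by the engine).
    """
    if redetect_result is None:
        return {"blink": True, "method": "blink", "pupil": None}
    return {"blink": False, "method": "hough_fallback", "pupil": redetect_result}
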