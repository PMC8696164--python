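"""Frame conditioning: Gaussian smoothing, thresholding, parameter estimation.

The walk-out operates on a 0/1 transform in which the target blob (pupil
or glint) is the 1-class.  Processing order is fixed as smooth -> binarize;
smoothing a binary image would destroy the 0/1 contract the edge walker
relies on.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

from .core import BinaryFrame, PreprocParams, VideoFrame
from .errors import DegenerateFrameError

__all__ = ["estimate_params", "smooth", "binarize", "histogram"]


def histogram(frame: VideoFrame) -> np.ndarray:
    """256-bin intensity histogram of a frame."""
    return np.bincount(
        np.clip(np.asarray(frame.pixels), 0, 255).astype(np.uint8).ravel(), minlength=256
    )


def estimate_params(frame: VideoFrame, seed: tuple[int, int] | None = None) -> PreprocParams:
    """Propose thresholding parameters from the pixel distribution.

    The pupil threshold is Otsu's between-class optimum.  ``invert`` is
    chosen so the blob containing ``seed`` maps to 1; without a seed,
    dark-pupil (IR) imaging is assumed and the dark class becomes the
    target.  The glint threshold is placed halfway between the pupil
    threshold and the frame maximum, since corneal reflections are the
    brightest structures in an IR frame.  All values are starting points
    and user-overridable.
    """
    px = np.asarray(frame.pixels, dtype=float)
    if np.ptp(px) == 0:
        raise DegenerateFrameError("constant-intensity frame has no distribution to threshold")
    thr = float(threshold_otsu(px))
    if seed is not None:
        x, y = int(round(seed[0])), int(round(seed[1]))
        invert = bool(px[y, x] <= thr)
    else:
        invert = True
    cr_thr = min(255.0, 0.5 * (thr + float(px.max())))
    return PreprocParams(threshold=thr, invert=invert, gaussian_sigma=2.0, cr_threshold=cr_thr)


def smooth(frame: VideoFrame, sigma: float) -> VideoFrame:
    """Gaussian blur with reflective borders; ``sigma == 0`` is the identity.

    Integer frames stay integer (rounded); float frames are filtered
    exactly, which conserves total intensity mass away from borders.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return frame
    px = np.asarray(frame.pixels)
    out = gaussian_filter(px.astype(float), sigma=sigma, mode="reflect")
    if np.issubdtype(px.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(px.dtype)
    return VideoFrame(pixels=out, index=frame.index, time_s=frame.time_s)


def binarize(frame: VideoFrame, params: PreprocParams, target: str = "pupil") -> BinaryFrame:
    """Threshold a frame so the target blob becomes the 1-class.

    ``target`` selects the (threshold, invert) pair: ``"pupil"`` or
    ``"cr"``.  With ``invert`` the 1-class is ``intensity <= threshold``,
    otherwise ``intensity >= threshold``.
    """
    if target == "pupil":
        thr, inv = params.threshold, params.invert
    elif target == "cr":
        thr, inv = params.cr_threshold, params.cr_invert
    else:
        raise ValueError("target must be 'pupil' or 'cr'")
    px = np.asarray(frame.pixels, dtype=float)
    mask = px <= thr if inv else px >= thr
    return BinaryFrame(pixels=mask.astype(np.uint8))
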