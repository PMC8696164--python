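"""Independent reference implementations used as test oracles.

These deliberately use the slowest, most literal formulation of each rule
so they stay independent of the vectorized code paths they check.
"""

from __future__ import annotations

import numpy as np


def naive_walk_out(binary: np.ndarray, seed: tuple[int, int], directions) -> dict:
    """Per-pixel iterative walker: step one lattice point at a time.

    Returns {direction_index: (x, y) subpixel midpoint} for each ray that
    meets a 0-pixel before leaving the frame.
    """
    h, w = binary.shape
    x0, y0 = seed
    out = {}
    for i, (dx, dy) in enumerate(directions):
        k = 0
        x, y = x0, y0
        while True:
            k += 1
            x, y = x0 + k * dx, y0 + k * dy
            if not (0 <= x < w and 0 <= y < h):
                break
            if binary[y, x] == 0:
                out[i] = (x0 + (k - 0.5) * dx, y0 + (k - 0.5) * dy)
                break
    return out


def random_blob(rng: np.random.Generator, max_side: int = 128) -> tuple[np.ndarray, tuple[int, int]]:
    """Random binary blob (union of disks, optional holes) plus an interior seed."""
    h = int(rng.integers(32, max_side + 1))
    w = int(rng.integers(32, max_side + 1))
    img = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[:h, :w]
    cx0 = int(rng.integers(w // 4, 3 * w // 4))
    cy0 = int(rng.integers(h // 4, 3 * h // 4))
    r0 = int(rng.integers(5, max(6, min(h, w) // 4)))
    img[(xx - cx0) ** 2 + (yy - cy0) ** 2 <= r0 * r0] = 1
    for _ in range(int(rng.integers(0, 3))):  # extra lobes
        cx = cx0 + int(rng.integers(-r0, r0 + 1))
        cy = cy0 + int(rng.integers(-r0, r0 + 1))
        r = int(rng.integers(3, r0 + 1))
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = 1
    for _ in range(int(rng.integers(0, 3))):  # glint-like holes
        cx = cx0 + int(rng.integers(-r0, r0 + 1))
        cy = cy0 + int(rng.integers(-r0, r0 + 1))
        r = int(rng.integers(1, 4))
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = 0
    img[cy0, cx0] = 1  # guarantee an on-blob interior seed
    return img, (cx0, cy0)


def one_sd_filter_oracle(points: np.ndarray) -> np.ndarray:
    """Literal restatement of the occlusion rule, scalar arithmetic only."""
    pts = np.asarray(points, dtype=float)
    mx = sum(p[0] for p in pts) / len(pts)
    my = sum(p[1] for p in pts) / len(pts)
    d = [((p[0] - mx) ** 2 + (p[1] - my) ** 2) ** 0.5 for p in pts]
    mean_d = sum(d) / len(d)
    sd = (sum((di - mean_d) ** 2 for di in d) / len(d)) ** 0.5
    return np.array([abs(di - mean_d) <= sd for di in d])


def titrate_filter_cutoff(ks=(0.5, 0.9, 1.1, 2.0)) -> tuple[float, float]:
    """Bracket the occlusion-filter discard cutoff in SD units.

    Places 31 points on a circle of radius 10 plus one probe whose
    distance deviates from the mean by exactly ``k`` standard deviations
    of the full set (the probe radius solving that self-consistency is
    found by bisection), runs the filter, and returns (largest kept k,
    smallest discarded k).
    """
    from ocutrack.core import ContourPointSet
    from ocutrack.shape_fitting import filter_contour

    theta = np.linspace(0.0, 2.0 * np.pi, 32)[:-1]
    base = np.column_stack([10.0 * np.cos(theta), 10.0 * np.sin(theta)])

    def realized_k(delta: float) -> float:
        pts = np.vstack([base, [10.0 + delta, 0.0]])
        m = pts.mean(axis=0)
        d = np.hypot(pts[:, 0] - m[0], pts[:, 1] - m[1])
        return abs(d[-1] - d.mean()) / d.std()

    def solve_delta(k: float) -> float:
        lo, hi = 0.3, 8.0  # realized k rises monotonically on this branch
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if realized_k(mid) < k:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    max_kept = -np.inf
    min_discarded = np.inf
    for k in ks:
        delta = solve_delta(k)
        pts = np.vstack([base, [10.0 + delta, 0.0]])
        cps = ContourPointSet(points=pts, ray_ids=np.arange(32), kept=np.ones(32, bool))
        filtered, _ = filter_contour(cps)
        if filtered.kept[-1]:
            max_kept = max(max_kept, k)
        else:
            min_discarded = min(min_discarded, k)
    return float(max_kept), float(min_discarded)
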