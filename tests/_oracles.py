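"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: direct
fixed-point iteration for the minimum-cross-entropy threshold, exhaustive
perfect-matching enumeration, polygon hulls on pixel corners, angular
occupancy scans for ring-arc counting, and all-pairs boundary distances.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull


def li_threshold_fixed_point(image: np.ndarray, tol: float = 1e-8) -> float:
    """Direct fixed-point iteration of the minimum-cross-entropy
    criterion: t <- (mu_bg - mu_fg) / (ln mu_bg - ln mu_fg) with the
    means taken below/above t. Requires positive data."""
    values = np.asarray(image, dtype=float).ravel()
    assert values.min() > 0, "oracle requires positive values"
    t = values.mean()
    for _ in range(1000):
        below = values[values <= t]
        above = values[values > t]
        if below.size == 0 or above.size == 0:
            break
        mu_b, mu_f = below.mean(), above.mean()
        t_new = (mu_b - mu_f) / (np.log(mu_b) - np.log(mu_f))
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    return t


def enumerate_perfect_matchings(n: int):
    """All perfect matchings of {0..n-1} as lists of index pairs."""

    def rec(idx):
        if not idx:
            yield []
            return
        a = idx[0]
        for i in range(1, len(idx)):
            b = idx[i]
            rest = idx[1:i] + idx[i + 1 :]
            for rest_match in rec(rest):
                yield [(a, b)] + rest_match

    yield from rec(list(range(n)))


def optimal_matching_cost(dist: np.ndarray) -> float:
    """Exhaustive minimum total distance over all perfect matchings."""
    n = dist.shape[0]
    return min(
        sum(dist[i, j] for i, j in match) for match in enumerate_perfect_matchings(n)
    )


def crossmatch_counts_by_enumeration(m: int, n: int) -> dict[int, float]:
    """Frequency of the cross-match count over all perfect matchings of
    m + n points with the first m in group 0."""
    labels = [0] * m + [1] * n
    counts: dict[int, int] = {}
    total = 0
    for match in enumerate_perfect_matchings(m + n):
        a1 = sum(1 for i, j in match if labels[i] != labels[j])
        counts[a1] = counts.get(a1, 0) + 1
        total += 1
    return {a1: c / total for a1, c in counts.items()}


def pixel_corner_hull_area(mask: np.ndarray, pixel_size: float) -> float:
    """Exact convex-hull area over the four corners of every foreground
    pixel (shoelace via scipy's qhull)."""
    rows, cols = np.nonzero(mask)
    corners = np.concatenate(
        [
            np.stack([rows, cols], axis=1),
            np.stack([rows + 1, cols], axis=1),
            np.stack([rows, cols + 1], axis=1),
            np.stack([rows + 1, cols + 1], axis=1),
        ]
    ).astype(float)
    hull = ConvexHull(corners)
    return hull.volume * pixel_size**2  # 2-D "volume" is the area


def angular_arc_count(
    mask: np.ndarray, center: tuple[float, float], radius_px: float, n_samples: int = 4096
) -> int:
    """Count connected angular runs of mask coverage on one circle, with
    wraparound, by dense polar sampling (nearest-pixel lookup)."""
    cy, cx = center
    thetas = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    ys = np.clip(np.round(cy + radius_px * np.sin(thetas)).astype(int), 0, mask.shape[0] - 1)
    xs = np.clip(np.round(cx + radius_px * np.cos(thetas)).astype(int), 0, mask.shape[1] - 1)
    covered = mask[ys, xs]
    if covered.all():
        return 1
    if not covered.any():
        return 0
    transitions = np.flatnonzero(covered & ~np.roll(covered, 1))
    return len(transitions)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one non-foreground 8-neighbour."""
    padded = np.pad(mask, 1)
    out = np.zeros_like(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        patch = padded[r : r + 3, c : c + 3]
        if not patch.all():
            out[r, c] = True
    return out


def directed_hausdorff_bruteforce(
    from_mask: np.ndarray, to_mask: np.ndarray, pixel_size: float
) -> float:
    """max over boundary pixels of from_mask of the min distance to the
    boundary of to_mask (plain double loop)."""
    src = np.argwhere(boundary_pixels(from_mask)).astype(float)
    dst = np.argwhere(boundary_pixels(to_mask)).astype(float)
    best = 0.0
    for p in src:
        d = np.sqrt(((dst - p) ** 2).sum(axis=1)).min()
        best = max(best, d)
    return best * pixel_size


def occupancy_fixed_mask(masks: np.ndarray, threshold: float) -> np.ndarray:
    """Per-pixel occupancy loop: fixed = covered in >= ceil(thr*T) frames."""
    T = masks.shape[0]
    need = int(np.ceil(threshold * T - 1e-9))
    counts = np.zeros(masks.shape[1:], dtype=int)
    for frame in masks:
        counts += frame.astype(int)
    return counts >= need
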