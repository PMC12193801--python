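"""Ground-truthed synthetic inputs for every pipeline stage.

Simulated sessile cells consist of a temporally fixed elliptical core
plus capsule-shaped protrusions whose lengths oscillate sinusoidally,
rasterized at a configurable pixel size and frame interval. Tissue
movies add probability-map blur and noise; feature populations are
multivariate Gaussians for exercising the comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .features import CellMovie
from .io_config import Calibration, Movie, get_logger

__all__ = [
    "SyntheticCellParams",
    "GroundTruth",
    "simulate_cell_movie",
    "simulate_tissue_movie",
    "simulate_feature_population",
    "default_cell_params",
    "default_tissue_params",
]

logger = get_logger(__name__)

_MARGIN_UM = 2.0


@dataclass(frozen=True)
class SyntheticCellParams:
    """Geometry and dynamics of one simulated cell.

    The cell is an ellipse (semi-axes ``core_semi_axes_um``) with
    ``n_protrusions`` capsules anchored on its boundary at angles
    ``angles_rad``; protrusion *k* has length
    ``L_k(t) = base_length_um + amplitude_um · sin(2π t / period_s + φ_k)``.
    Angles/phases default to evenly spaced angles and seeded random
    phases. Everything is deterministic given the seed.
    """

    core_semi_axes_um: tuple[float, float] = (8.0, 6.0)
    center_um: tuple[float, float] | None = None  # (y, x); None → frame center
    n_protrusions: int = 5
    protrusion_width_um: float = 3.0
    base_length_um: float = 8.0
    amplitude_um: float = 4.0
    period_s: float = 120.0
    duration_s: float = 600.0
    angles_rad: tuple[float, ...] | None = None
    phases_rad: tuple[float, ...] | None = None
    calibration: Calibration = field(
        default_factory=lambda: Calibration(pixel_size_um=0.55, frame_interval_s=14.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.core_semi_axes_um
        if a <= 0 or b <= 0:
            raise ValueError("core semi-axes must be positive")
        if self.n_protrusions < 0:
            raise ValueError("n_protrusions must be >= 0")
        if self.n_protrusions > 0:
            if self.protrusion_width_um <= 0:
                raise ValueError("protrusion width must be positive")
            if self.base_length_um <= 0:
                raise ValueError("base length must be positive")
        if self.amplitude_um < 0:
            raise ValueError("amplitude must be >= 0")
        if self.base_length_um - self.amplitude_um < 0:
            raise ValueError("base_length_um - amplitude_um must be >= 0")
        if self.period_s <= 0 or self.duration_s <= 0:
            raise ValueError("period and duration must be positive")

    @property
    def max_extent_um(self) -> float:
        """Largest distance from the center the cell can ever reach."""
        a, b = self.core_semi_axes_um
        reach = max(a, b)
        if self.n_protrusions > 0:
            reach = max(
                reach,
                max(a, b)
                + self.base_length_um
                + self.amplitude_um
                + self.protrusion_width_um / 2,
            )
        return reach


@dataclass
class GroundTruth:
    """Analytic truth accompanying a simulated cell movie."""

    core_mask: np.ndarray
    masks: np.ndarray  # identical to the rasterized cell movie
    tip_positions_um: np.ndarray  # (T, K, 2) (y, x) per frame per protrusion
    analytic_areas_um2: np.ndarray  # closed-form core+lobe area per frame
    protrusion_lengths_um: np.ndarray  # (T, K)


def _resolve_angles_phases(params: SyntheticCellParams) -> tuple[np.ndarray, np.ndarray]:
    K = params.n_protrusions
    rng = np.random.default_rng(params.seed)
    if params.angles_rad is not None:
        angles = np.asarray(params.angles_rad, dtype=float)
    else:
        angles = np.linspace(0, 2 * np.pi, K, endpoint=False)
        angles = angles + rng.uniform(-0.15, 0.15, size=K)
    if params.phases_rad is not None:
        phases = np.asarray(params.phases_rad, dtype=float)
    else:
        phases = rng.uniform(0, 2 * np.pi, size=K)
    if len(angles) != K or len(phases) != K:
        raise ValueError("angles/phases must have one entry per protrusion")
    return angles, phases


def _ellipse_boundary_point(a: float, b: float, theta: float) -> np.ndarray:
    """Point on the ellipse boundary along direction theta (y, x)."""
    c, s = np.cos(theta), np.sin(theta)
    r = 1.0 / np.sqrt((c / a) ** 2 + (s / b) ** 2)
    return np.array([r * s, r * c])  # (y, x)


def _auto_frame_shape(params: SyntheticCellParams) -> tuple[int, int]:
    px = params.calibration.pixel_size_um
    side = int(np.ceil(2 * (params.max_extent_um + _MARGIN_UM) / px))
    return (side, side)


def simulate_cell_movie(
    params: SyntheticCellParams,
    frame_shape: tuple[int, int] | None = None,
) -> tuple[CellMovie, GroundTruth]:
    """Rasterize one cell movie plus its analytic ground truth.

    Capsules are anchored w/2 inside the core boundary so that a fully
    retracted protrusion (L = 0) hides inside the core. The closed-form
    area law is ellipse + Σ_k (w·L_k(t) + π(w/2)²/2 − w²/2): rectangle
    plus far half-cap, minus the part behind the core boundary.
    """
    cal = params.calibration
    px = cal.pixel_size_um
    if frame_shape is None:
        frame_shape = _auto_frame_shape(params)
    H, W = frame_shape

    if params.center_um is None:
        center = np.array([H * px / 2, W * px / 2])
    else:
        center = np.asarray(params.center_um, dtype=float)

    needed = params.max_extent_um + _MARGIN_UM
    cy, cx = center
    if (
        cy - needed < 0
        or cx - needed < 0
        or cy + needed > H * px
        or cx + needed > W * px
    ):
        side = int(np.ceil(2 * needed / px))
        raise ValueError(
            f"cell geometry exceeds the frame; use a frame of at least "
            f"({side}, {side}) pixels or recenter the cell"
        )

    T = int(np.floor(params.duration_s / cal.frame_interval_s)) + 1
    times = np.arange(T) * cal.frame_interval_s
    a, b = params.core_semi_axes_um
    w = params.protrusion_width_um
    K = params.n_protrusions
    angles, phases = _resolve_angles_phases(params)

    # pixel-center coordinates in μm
    yy, xx = np.indices((H, W), dtype=float)
    Y = (yy + 0.5) * px - cy
    X = (xx + 0.5) * px - cx

    core = (X / a) ** 2 + (Y / b) ** 2 <= 1.0

    dirs = np.array([[np.sin(th), np.cos(th)] for th in angles]).reshape(K, 2)
    anchors = np.array(
        [
            _ellipse_boundary_point(a, b, th) - (w / 2) * u
            for th, u in zip(angles, dirs)
        ]
    ).reshape(K, 2)

    masks = np.empty((T, H, W), dtype=bool)
    tips = np.zeros((T, K, 2))
    lengths = np.zeros((T, K))
    analytic = np.zeros(T)
    ellipse_area = np.pi * a * b
    cap_half = np.pi * (w / 2) ** 2 / 2

    for t_idx, t in enumerate(times):
        mask = core.copy()
        for k in range(K):
            L = params.base_length_um + params.amplitude_um * np.sin(
                2 * np.pi * t / params.period_s + phases[k]
            )
            lengths[t_idx, k] = L
            p0 = anchors[k]
            u = dirs[k]
            tips[t_idx, k] = center + p0 + L * u
            # distance of each pixel to the segment p0 -> p0 + L*u
            ry = Y - p0[0]
            rx = X - p0[1]
            proj = np.clip(ry * u[0] + rx * u[1], 0.0, L)
            d2 = (ry - proj * u[0]) ** 2 + (rx - proj * u[1]) ** 2
            mask |= d2 <= (w / 2) ** 2
        masks[t_idx] = mask
        analytic[t_idx] = ellipse_area + (
            w * lengths[t_idx].sum() + K * (cap_half - w**2 / 2)
        )

    movie = CellMovie(masks=masks, calibration=cal, cell_id=1)
    truth = GroundTruth(
        core_mask=core,
        masks=masks,
        tip_positions_um=tips,
        analytic_areas_um2=analytic,
        protrusion_lengths_um=lengths,
    )
    return movie, truth


def simulate_tissue_movie(
    cells: list[SyntheticCellParams],
    frame_shape: tuple[int, int],
    calibration: Calibration | None = None,
    p_fg: float = 0.9,
    p_bg: float = 0.1,
    blur_sigma_px: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[Movie, Movie, list[GroundTruth]]:
    """Compose several cells into a probability-map movie.

    Returns ``(probability movie, ground-truth label movie, truths)``.
    Cell cores must not overlap; overlapping protrusion pixels are
    assigned to the lowest label and logged. The probability map is
    ``p_fg`` on cells and ``p_bg`` elsewhere, Gaussian-blurred with
    ``blur_sigma_px`` and perturbed by seeded Gaussian noise, clipped to
    [0, 1].
    """
    if not cells:
        raise ValueError("need at least one cell")
    calibration = calibration or cells[0].calibration
    sims = [
        simulate_cell_movie(replace(p, calibration=calibration), frame_shape)
        for p in cells
    ]
    cores = [truth.core_mask for _, truth in sims]
    for i in range(len(cores)):
        for j in range(i + 1, len(cores)):
            if (cores[i] & cores[j]).any():
                raise ValueError(f"cores of cells {i} and {j} overlap")

    T = sims[0][0].n_frames
    H, W = frame_shape
    labels = np.zeros((T, H, W), dtype=np.int32)
    overlap_px = 0
    for idx, (cell, _) in enumerate(sims, start=1):
        taken = labels > 0
        overlap_px += int((cell.masks & taken).sum())
        labels[cell.masks & ~taken] = idx
    if overlap_px:
        logger.info(
            "simulate_tissue_movie: %d overlapping protrusion pixels assigned "
            "to the lower label",
            overlap_px,
        )

    rng = np.random.default_rng(seed)
    prob = np.where(labels > 0, p_fg, p_bg).astype(np.float64)
    if blur_sigma_px > 0:
        prob = np.stack([ndi.gaussian_filter(f, blur_sigma_px) for f in prob])
    if noise_sd > 0:
        prob = prob + rng.normal(0.0, noise_sd, size=prob.shape)
    prob = np.clip(prob, 0.0, 1.0)
    return (
        Movie(prob, calibration),
        Movie(labels, calibration),
        [truth for _, truth in sims],
    )


def simulate_feature_population(
    m: int,
    n: int,
    dims: int,
    shift: float | np.ndarray = 0.0,
    covariance: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian feature populations A ~ N(0, Σ), B ~ N(μ, Σ).

    A scalar ``shift`` is interpreted as the Mahalanobis distance
    between the means, spread equally over all dimensions; a vector is
    used as the mean directly. Σ defaults to the identity and must be
    positive definite.
    """
    if m < 1 or n < 1 or dims < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    if covariance is None:
        L = np.eye(dims)
        cov = np.eye(dims)
    else:
        cov = np.asarray(covariance, dtype=float)
        if cov.shape != (dims, dims):
            raise ValueError("covariance shape mismatch")
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
    if np.isscalar(shift):
        mu = _mahala_mean(float(shift), cov)
    else:
        mu = np.asarray(shift, dtype=float)
        if mu.shape != (dims,):
            raise ValueError("shift vector shape mismatch")
    A = rng.standard_normal((m, dims)) @ L.T
    B = rng.standard_normal((n, dims)) @ L.T + mu
    return A, B


def _mahala_mean(delta: float, cov: np.ndarray) -> np.ndarray:
    """Mean vector at Mahalanobis distance delta along the equal-weight
    direction for a general covariance."""
    d = cov.shape[0]
    v = np.ones(d)
    denom = np.sqrt(v @ np.linalg.solve(cov, v))
    return delta * v / denom


def default_cell_params(seed: int = 0) -> SyntheticCellParams:
    """Desk-scale single-cell preset."""
    return SyntheticCellParams(seed=seed)


def default_tissue_params(
    seed: int = 0, frame_shape: tuple[int, int] = (280, 280)
) -> list[SyntheticCellParams]:
    """Three well-separated cells for the tissue preset."""
    cal = Calibration(pixel_size_um=0.45, frame_interval_s=14.0)
    px = cal.pixel_size_um
    H, W = frame_shape
    span_y, span_x = H * px, W * px
    centers = [
        (span_y * 0.27, span_x * 0.27),
        (span_y * 0.27, span_x * 0.73),
        (span_y * 0.73, span_x * 0.50),
    ]
    return [
        SyntheticCellParams(
            core_semi_axes_um=(10.0, 8.0),
            center_um=c,
            n_protrusions=4,
            protrusion_width_um=3.0,
            base_length_um=6.0,
            amplitude_um=6.0,
            period_s=120.0,
            duration_s=600.0,
            calibration=cal,
            seed=seed + i,
        )
        for i, c in enumerate(centers)
    ]
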