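"""Turn a 2D+T probability-map movie into per-cell binary movies.

Stages: Li minimum-cross-entropy binarization per frame, morphological
cleanup (opening, hole filling, speck removal), temporally integrated
seed extraction at a 0.97 occupancy threshold, a two-pass seeded
watershed with a diamond dilation that re-attaches protrusion fragments,
and a file-driven curation step (merge/exclude of seed labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation

from .features import CellMovie
from .io_config import Calibration, Movie, PipelineConfig, get_logger

__all__ = [
    "SeedLabels",
    "CurationSpec",
    "binarize_movie",
    "clean_binary_frame",
    "clean_binary_movie",
    "seed_labels",
    "label_cells",
    "curate_labels",
    "extract_cell_movies",
]

logger = get_logger(__name__)

# 8-neighbor connectivity throughout: thin diagonal protrusions must stay
# connected to their cell body.
_CONN = 2


@dataclass
class SeedLabels:
    """Static seed label grid plus the area of each label."""

    labels: np.ndarray  # (Y, X) int, 0 = background
    areas_um2: dict[int, float] = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class CurationSpec:
    """Manual-curation instructions: seed labels to merge or drop."""

    merge: list[list[int]] = field(default_factory=list)
    exclude: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for group in self.merge:
            for label in group:
                if label in seen:
                    raise ValueError(f"label {label} appears in more than one merge group")
                seen.add(label)

    @classmethod
    def from_file(cls, path) -> "CurationSpec":
        import json
        from pathlib import Path

        data = json.loads(Path(path).read_text())
        return cls(merge=data.get("merge", []), exclude=data.get("exclude", []))


def binarize_movie(prob_movie: Movie, global_threshold: bool = False) -> Movie:
    """Binarize each frame with Li's iterative minimum-cross-entropy
    threshold; foreground = values ≥ threshold.

    Constant frames admit no threshold: they are returned empty with a
    warning. With ``global_threshold`` a single threshold is computed on
    the pooled movie (for flickering exposures).
    """
    data = np.asarray(prob_movie.data, dtype=np.float64)
    out = np.zeros(data.shape, dtype=bool)
    if global_threshold:
        if np.ptp(data) == 0:
            logger.warning("constant movie: no global threshold exists")
            return Movie(out, prob_movie.calibration)
        thr = filters.threshold_li(data)
        out = data >= thr
        return Movie(out, prob_movie.calibration)
    for t, frame in enumerate(data):
        if np.ptp(frame) == 0:
            logger.warning("frame %d is constant; returned empty", t)
            continue
        thr = filters.threshold_li(frame)
        out[t] = frame >= thr
    return Movie(out, prob_movie.calibration)


def _remove_small(mask: np.ndarray, min_area_um2: float, cal: Calibration) -> np.ndarray:
    """Drop 8-connected foreground components with area < min_area_um2."""
    labels = measure.label(mask, connectivity=_CONN)
    if labels.max() == 0:
        return mask
    areas = np.bincount(labels.ravel())[1:] * cal.pixel_area_um2
    keep = np.flatnonzero(areas >= min_area_um2) + 1
    return np.isin(labels, keep)


def clean_binary_frame(
    mask: np.ndarray, config: PipelineConfig, calibration: Calibration
) -> np.ndarray:
    """Smooth one binary frame: opening with a disk of
    ``opening_radius_um``, then fill holes smaller than
    ``min_hole_area_um2``, then remove objects smaller than
    ``min_object_area_um2``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    r = calibration.radius_px(config.opening_radius_um)
    opened = morphology.opening(mask, footprint=morphology.disk(r))
    # fill small holes: background components not touching the border
    inv = ~opened
    holes = measure.label(inv, connectivity=1)
    border_labels = np.unique(
        np.concatenate([holes[0], holes[-1], holes[:, 0], holes[:, -1]])
    )
    filled = opened.copy()
    for lbl in range(1, holes.max() + 1):
        if lbl in border_labels:
            continue
        area = calibration.area_um2(int((holes == lbl).sum()))
        if area < config.min_hole_area_um2:
            filled[holes == lbl] = True
    return _remove_small(filled, config.min_object_area_um2, calibration)


def clean_binary_movie(binary_movie: Movie, config: PipelineConfig) -> Movie:
    cleaned = np.stack(
        [
            clean_binary_frame(f, config, binary_movie.calibration)
            for f in binary_movie.data
        ]
    )
    return Movie(cleaned, binary_movie.calibration)


def seed_labels(binary_movie: Movie, config: PipelineConfig) -> SeedLabels:
    """Seed labels from the time-integrated movie.

    Pixels foreground in at least ``fixed_threshold`` of the frames form
    the seed mask; components below ``seed_min_area_um2`` are removed
    and the remainder labeled 1..K.
    """
    cal = binary_movie.calibration
    occupancy = binary_movie.data.astype(bool).mean(axis=0)
    seed_mask = occupancy >= config.fixed_threshold - 1e-12
    seed_mask = _remove_small(seed_mask, config.seed_min_area_um2, cal)
    labels = measure.label(seed_mask, connectivity=_CONN)
    areas = {
        lbl: cal.area_um2(int((labels == lbl).sum()))
        for lbl in range(1, labels.max() + 1)
    }
    if labels.max() == 0:
        logger.warning("empty seed mask: no cells will be labeled")
    logger.info("seed_labels: %d seeds", labels.max())
    return SeedLabels(labels=labels, areas_um2=areas)


def _elevation(binary: np.ndarray, prob_frame: np.ndarray | None) -> np.ndarray:
    """Watershed elevation: negated probability map when available, else
    the negated distance transform of the mask being flooded."""
    if prob_frame is not None:
        return -np.asarray(prob_frame, dtype=np.float64)
    return -ndi.distance_transform_edt(binary)


def label_cells(
    binary_movie: Movie,
    seeds: SeedLabels,
    config: PipelineConfig,
    prob_movie: Movie | None = None,
) -> Movie:
    """Two-pass seeded watershed labeling of each frame.

    Per frame: (i) watershed restricted to the cleaned foreground from
    the static seeds; (ii) dilate the foreground with a diamond of
    ``dilation_radius_um`` and watershed again seeded by (i), which
    re-attaches protrusion fragments within the dilation reach; (iii)
    intersect the result with the cleaned foreground. Foreground that no
    seed can reach even after dilation stays background and is logged.
    """
    if seeds.labels.shape != binary_movie.frame_shape:
        raise ValueError(
            f"seed shape {seeds.labels.shape} != movie frame shape "
            f"{binary_movie.frame_shape}"
        )
    cal = binary_movie.calibration
    r = cal.radius_px(config.dilation_radius_um)
    diamond = morphology.diamond(r)
    out = np.zeros(binary_movie.data.shape, dtype=np.int32)
    unassigned_total = 0
    for t, frame in enumerate(binary_movie.data):
        binary = frame.astype(bool)
        if not binary.any():
            continue
        prob = prob_movie.data[t] if prob_movie is not None else None
        ws1 = segmentation.watershed(
            _elevation(binary, prob), markers=seeds.labels, mask=binary, connectivity=_CONN
        )
        dilated = morphology.dilation(binary, footprint=diamond)
        ws2 = segmentation.watershed(
            _elevation(dilated, prob), markers=ws1, mask=dilated, connectivity=_CONN
        )
        final = np.where(binary, ws2, 0)
        unassigned_total += int((binary & (final == 0)).sum())
        out[t] = final
    if unassigned_total:
        logger.info(
            "label_cells: %d foreground pixels unreachable from any seed "
            "left as background",
            unassigned_total,
        )
    return Movie(out, cal)


def curate_labels(
    labeled_movie: Movie, seeds: SeedLabels, spec: CurationSpec
) -> tuple[Movie, SeedLabels]:
    """Apply merge/exclude curation and relabel consecutively.

    Merge groups are unified to their smallest id; excluded labels become
    background everywhere. Labels touching the frame border are flagged
    in the log (border-cut cells are excluded by the user, never
    automatically).
    """
    existing = set(np.unique(labeled_movie.data)) | set(np.unique(seeds.labels))
    existing.discard(0)
    referenced = set(spec.exclude)
    for group in spec.merge:
        referenced |= set(group)
    unknown = referenced - existing
    if unknown:
        raise ValueError(f"curation references unknown labels: {sorted(unknown)}")

    max_label = int(max(existing, default=0))
    remap = np.arange(max_label + 1, dtype=np.int32)
    for group in spec.merge:
        target = min(group)
        for label in group:
            remap[label] = target
    for label in spec.exclude:
        remap[label] = 0
    # consecutive relabeling, ordered by surviving id
    survivors = sorted(set(remap[sorted(existing)]) - {0})
    final_map = np.zeros(max_label + 1, dtype=np.int32)
    for new, old in enumerate(survivors, start=1):
        final_map[old] = new
    full_map = final_map[remap]

    new_movie = Movie(full_map[labeled_movie.data], labeled_movie.calibration)
    new_seed_grid = full_map[seeds.labels]
    cal = labeled_movie.calibration
    areas = {
        int(lbl): cal.area_um2(int((new_seed_grid == lbl).sum()))
        for lbl in np.unique(new_seed_grid)
        if lbl != 0
    }

    border = np.zeros(labeled_movie.frame_shape, dtype=bool)
    border[0], border[-1], border[:, 0], border[:, -1] = True, True, True, True
    touching = set(np.unique(new_movie.data[:, border])) - {0}
    if touching:
        logger.warning("labels touching the frame border: %s", sorted(touching))
    logger.info(
        "curate_labels: %d labels in, %d labels out", len(existing), len(survivors)
    )
    return new_movie, SeedLabels(labels=new_seed_grid, areas_um2=areas)


def extract_cell_movies(labeled_movie: Movie) -> list[CellMovie]:
    """One binary CellMovie per label, ordered by label id.

    A label absent from some frame yields an empty mask there (recorded
    downstream as a flagged, zero-area frame).
    """
    labels = sorted(set(np.unique(labeled_movie.data)) - {0})
    cells = []
    for lbl in labels:
        masks = labeled_movie.data == lbl
        if not masks.all(axis=(1, 2)).any():
            empty_frames = np.flatnonzero(~masks.any(axis=(1, 2)))
            if empty_frames.size:
                logger.warning(
                    "label %d absent in %d frame(s)", lbl, empty_frames.size
                )
        cells.append(
            CellMovie(masks=masks, calibration=labeled_movie.calibration, cell_id=int(lbl))
        )
    return cells
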