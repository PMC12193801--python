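"""Calibrated movie/table I/O, pipeline configuration and logging.

All physical-unit parameters (μm, μm², s) are converted to pixel/frame
units exclusively through :class:`Calibration`, so that a single pixel
size and frame interval govern the whole pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Calibration",
    "PipelineConfig",
    "Movie",
    "read_movie",
    "write_movie",
    "read_table",
    "write_table",
    "get_logger",
]

_LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"


def get_logger(name: str = "morphodyn") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a 2D+T movie.

    Parameters
    ----------
    pixel_size_um : float
        Length of one pixel edge in μm. Must be strictly positive.
    frame_interval_s : float
        Time between consecutive frames in seconds. Must be strictly
        positive.
    """

    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise ValueError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def radius_px(self, radius_um: float) -> int:
        """Convert a radius in μm to pixels, rounding to the nearest
        integer but never below one pixel."""
        if radius_um <= 0:
            raise ValueError(f"radius must be > 0, got {radius_um}")
        return max(1, round(radius_um / self.pixel_size_um))

    def area_um2(self, n_pixels: int | np.integer | float) -> float:
        return float(n_pixels) * self.pixel_area_um2

    def length_um(self, n_pixels: float) -> float:
        return float(n_pixels) * self.pixel_size_um

    def lag_frames(self, lag_s: float) -> int:
        """Nearest frame count to a physical lag, minimum one frame."""
        if lag_s <= 0:
            raise ValueError(f"lag must be > 0, got {lag_s}")
        return max(1, round(lag_s / self.frame_interval_s))


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the segmentation/feature pipeline.

    Defaults reproduce the published processing parameters: a 0.97
    occupancy threshold for the fixed area and seeds, a 0.6 μm opening
    radius, 10 μm² hole/object filters, a 50 μm² seed-size filter, a
    2.2 μm diamond dilation, 8 μm Sholl ring steps and a 14 s lag for
    the dynamic area change.
    """

    fixed_threshold: float = 0.97
    opening_radius_um: float = 0.6
    min_hole_area_um2: float = 10.0
    min_object_area_um2: float = 10.0
    seed_min_area_um2: float = 50.0
    dilation_radius_um: float = 2.2
    sholl_step_um: float = 8.0
    dac_lag_s: float = 14.0
    angularity_radius_um: float = 1.0
    n_permutations: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fixed_threshold <= 1:
            raise ValueError("fixed_threshold must be in (0, 1]")
        for name in (
            "opening_radius_um",
            "min_hole_area_um2",
            "min_object_area_um2",
            "seed_min_area_um2",
            "dilation_radius_um",
            "sholl_step_um",
            "dac_lag_s",
            "angularity_radius_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yml", ".yaml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})


@dataclass
class Movie:
    """A 2D+T scalar movie with physical calibration.

    ``data`` has shape ``(T, Y, X)``. The dtype role (probability map,
    raw intensity, binary mask or integer labels) is carried by the
    array dtype and the producing stage; label movies use 0 as
    background.
    """

    data: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be (T, Y, X), got {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    def __iter__(self):
        return iter(self.data)


def read_movie(
    path: str | Path,
    calibration: Calibration,
    kind: str = "auto",
) -> Movie:
    """Read a multi-page TIFF into a :class:`Movie`.

    Values are preserved bit-for-bit, with one declared exception: with
    ``kind="probability"`` an integer-typed stack is rescaled to [0, 1]
    by the dtype maximum (8/16-bit exports of probability maps).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: pages have inconsistent shapes {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2D+T grayscale stack, got shape {data.shape}")
    if kind == "probability" and np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return Movie(data=data, calibration=calibration)


def write_movie(movie: Movie | np.ndarray, path: str | Path) -> Path:
    """Write a movie as a multi-page TIFF; pages follow frame order."""
    data = movie.data if isinstance(movie, Movie) else np.asarray(movie)
    if data.ndim == 2:
        data = data[None]
    if data.dtype == bool:
        data = data.astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def write_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Iterable[str] | None = None,
) -> Path:
    """Write rows as a CSV with a stable column order.

    ``rows`` may be a DataFrame or a sequence of mappings sharing one
    header schema; floats are serialized at full (round-trip) precision.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows:
            header = list(rows[0].keys())
            for r in rows[1:]:
                if list(r.keys()) != header:
                    raise ValueError("rows do not share a single header schema")
            frame = pd.DataFrame(rows, columns=header)
        else:
            frame = pd.DataFrame(columns=list(columns or []))
    if columns is not None:
        frame = frame.loc[:, list(columns)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return pd.read_csv(path)
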