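"""Camera geometry and temperature-matrix I/O.

Thermal cameras used in screening protocols image the patient at a fixed
stand-off distance; the thin-lens relation converts the sensor dimension
into the physical field of view, and hence into a metric pixel size on the
skin. All radial-profile machinery downstream works in metres, so getting
this scale right is what ties image offsets to heat-source depths.

Conventions: (row, col) indices are 0-based with row 0 at the image top;
temperature grids are plain whitespace-separated text, one image row per
line, '#'-prefixed header lines ignored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "CameraGeometry",
    "Thermogram",
    "DMR_IR_GEOMETRY",
    "InvalidGeometryError",
    "GridFormatError",
    "object_height",
    "pixel_size_object_plane",
    "read_temperature_matrix",
    "write_temperature_matrix",
    "read_grayscale_image",
    "load_camera_geometry",
]


class InvalidGeometryError(ValueError):
    """Camera geometry with non-positive lengths or zero pixel counts."""


class GridFormatError(ValueError):
    """Temperature grid file is ragged or contains non-numeric tokens."""


@dataclass(frozen=True)
class CameraGeometry:
    """Thin-lens imaging geometry of the thermal camera.

    Parameters
    ----------
    sensor_height_cm : vertical sensor dimension (cm).
    focal_length_cm : lens focal length (cm).
    object_distance_cm : camera-to-subject distance (cm).
    n_rows, n_cols : image resolution in pixels.
    """

    sensor_height_cm: float
    focal_length_cm: float
    object_distance_cm: float
    n_rows: int = 480
    n_cols: int = 640

    def __post_init__(self) -> None:
        for name in ("sensor_height_cm", "focal_length_cm", "object_distance_cm"):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidGeometryError("n_rows and n_cols must be >= 1")


#: FLIR SC-620 protocol geometry: 2.16 cm sensor height, 7.5 cm focal
#: length, 1 m stand-off, 640x480 frames.  Gives a 28.8 cm field of view
#: and a 0.06 cm (0.0006 m) pixel on the object plane.
DMR_IR_GEOMETRY = CameraGeometry(
    sensor_height_cm=2.16,
    focal_length_cm=7.5,
    object_distance_cm=100.0,
    n_rows=480,
    n_cols=640,
)


@dataclass
class Thermogram:
    """A per-pixel skin-temperature matrix with its physical metadata.

    Attributes
    ----------
    temperatures : (n_rows, n_cols) float array of degrees Celsius.
    pixel_size : metres per pixel on the object plane.
    ambient_temp : environment temperature Te in degrees Celsius.
    label : 'normal', 'abnormal' or None when unknown.
    """

    temperatures: np.ndarray
    pixel_size: float
    ambient_temp: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.ndim != 2 or self.temperatures.size == 0:
            raise ValueError("temperatures must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.temperatures)):
            raise ValueError("temperatures must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.label not in (None, "normal", "abnormal", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def shape(self) -> tuple:
        return self.temperatures.shape


def object_height(geom: CameraGeometry) -> float:
    """Field-of-view height on the object plane, in cm.

    Thin-lens scaling: lo = sensor_height / focal_length * object_distance.
    """
    return geom.sensor_height_cm / geom.focal_length_cm * geom.object_distance_cm


def pixel_size_object_plane(geom: CameraGeometry) -> float:
    """Physical size of one pixel on the object plane, in cm per pixel.

    The vertical axis is used (sensor height over row count); pixels are
    assumed square, consistent with a square detector pitch.
    """
    return object_height(geom) / geom.n_rows


def _parse_grid_text(text: str) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        try:
            rows.append([float(tok) for tok in tokens])
        except ValueError as exc:
            raise GridFormatError(f"non-numeric token on line {lineno}: {exc}") from exc
    if not rows:
        raise GridFormatError("no numeric rows found")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise GridFormatError(
                f"ragged grid: row {i} has {len(row)} tokens, expected {width}"
            )
    return np.asarray(rows, dtype=float)


def read_temperature_matrix(
    path: os.PathLike | str,
    geom: CameraGeometry = DMR_IR_GEOMETRY,
    ambient_temp: float = 22.0,
    label: Optional[str] = None,
) -> Thermogram:
    """Read a whitespace-separated temperature grid into a Thermogram.

    The pixel size is derived from ``geom`` and stored in metres. Row i of
    the file is image row i (top-down). Lines starting with '#' are skipped.
    """
    with open(path, "r", encoding="utf-8") as fh:
        matrix = _parse_grid_text(fh.read())
    return Thermogram(
        temperatures=matrix,
        pixel_size=pixel_size_object_plane(geom) / 100.0,  # cm -> m
        ambient_temp=ambient_temp,
        label=label,
    )


def write_temperature_matrix(thermogram: Thermogram, path: os.PathLike | str) -> None:
    """Write the temperature grid as text at full float precision."""
    np.savetxt(path, thermogram.temperatures, fmt="%.17g")


def read_grayscale_image(
    path: os.PathLike | str,
    t_min: float,
    t_max: float,
    geom: CameraGeometry = DMR_IR_GEOMETRY,
    ambient_temp: float = 22.0,
    label: Optional[str] = None,
) -> Thermogram:
    """Import a grayscale (8/16-bit) image with a linear temperature mapping.

    Pixel value 0 maps to ``t_min`` and the dtype maximum to ``t_max``.
    Intended for exports where the radiometric grid is unavailable.
    """
    from PIL import Image

    if t_max <= t_min:
        raise ValueError("t_max must exceed t_min")
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise GridFormatError("grayscale import requires a single-channel image")
    full_scale = float(np.iinfo(arr.dtype).max) if arr.dtype.kind in "iu" else 1.0
    temps = t_min + (arr.astype(float) / full_scale) * (t_max - t_min)
    return Thermogram(
        temperatures=temps,
        pixel_size=pixel_size_object_plane(geom) / 100.0,
        ambient_temp=ambient_temp,
        label=label,
    )


def load_camera_geometry(path: os.PathLike | str) -> CameraGeometry:
    """Load a camera-geometry block from a YAML config.

    Missing keys fall back to the default screening-protocol values.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    block = cfg.get("camera", cfg)
    return CameraGeometry(
        sensor_height_cm=float(block.get("sensor_height_cm", DMR_IR_GEOMETRY.sensor_height_cm)),
        focal_length_cm=float(block.get("focal_length_cm", DMR_IR_GEOMETRY.focal_length_cm)),
        object_distance_cm=float(block.get("object_distance_cm", DMR_IR_GEOMETRY.object_distance_cm)),
        n_rows=int(block.get("n_rows", DMR_IR_GEOMETRY.n_rows)),
        n_cols=int(block.get("n_cols", DMR_IR_GEOMETRY.n_cols)),
    )
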