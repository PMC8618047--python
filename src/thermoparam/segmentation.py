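"""Breast segmentation, hotspot location and radial temperature profiles.

The breast region is delimited by cubic-polynomial fits to annotated
inframammary-fold points; everything below the fold is masked out.  The
hottest masked pixel anchors a region of interest, and the surface
temperature distribution T(a) is the mean of four axis-aligned thermal
rays (up, down, left, right) sampled at integer pixel offsets from that
anchor.  Because the offset step equals one pixel exactly, sampling stays
on-lattice and needs no interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .optics import Thermogram

__all__ = [
    "BreastMask",
    "RoIProfile",
    "InsufficientPointsError",
    "EmptyMaskError",
    "DegenerateProfileError",
    "fit_inframammary_curve",
    "build_mask",
    "locate_hotspot",
    "extract_std_profile",
    "delta_T",
    "quantize_thermal_levels",
    "save_profile",
    "load_profile",
    "MAX_PROFILE_EXTENT_M",
]

#: Radial profiles are limited to 1.8 cm because hotspots sit close to the
#: image/mask boundary in frontal views; beyond this the rays run out.
MAX_PROFILE_EXTENT_M = 0.018


class InsufficientPointsError(ValueError):
    """Fewer than four distinct-column points for a cubic fit."""


class EmptyMaskError(ValueError):
    """Segmentation produced a mask with no pixels."""


class DegenerateProfileError(ValueError):
    """No valid radial offset beyond the hotspot itself."""


@dataclass
class BreastMask:
    """Boolean breast mask plus the inframammary curve(s) that cut it."""

    mask: np.ndarray
    curve_coeffs: Sequence[np.ndarray]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptyMaskError("mask has no true pixel")


@dataclass
class RoIProfile:
    """Mean radial surface-temperature distribution around the hotspot.

    offsets[k] = k * pixel_size (metres); mean_temp[k] is the average of
    the directions still inside the image and mask at offset k, and
    n_directions[k] counts them.  mean_temp[0] equals Tmax by definition.
    """

    offsets: np.ndarray
    mean_temp: np.ndarray
    tmax: float
    hotspot: Tuple[int, int]
    te: float
    n_directions: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.mean_temp = np.asarray(self.mean_temp, dtype=float)
        self.n_directions = np.asarray(self.n_directions, dtype=int)
        if not (len(self.offsets) == len(self.mean_temp) == len(self.n_directions)):
            raise ValueError("profile arrays must have equal length")
        if self.offsets[0] != 0.0:
            raise ValueError("offset grid must start at 0")
        if self.mean_temp[0] != self.tmax:
            raise ValueError("mean_temp[0] must equal Tmax")
        if np.any(self.n_directions < 1):
            raise ValueError("every retained offset needs >= 1 direction")

    @property
    def pixel_size(self) -> float:
        return float(self.offsets[1] - self.offsets[0]) if len(self.offsets) > 1 else 0.0

    def index_of(self, a: float, atol: float = 1e-12) -> int:
        """Index of offset ``a`` on the grid; raises if off-grid."""
        hits = np.nonzero(np.isclose(self.offsets, a, rtol=0.0, atol=atol))[0]
        if len(hits) == 0:
            raise ValueError(f"offset {a} m is not on the profile grid")
        return int(hits[0])


def fit_inframammary_curve(points: Sequence[Tuple[float, float]]) -> np.ndarray:
    """Least-squares cubic row = p(col) through annotated fold points.

    Returns polynomial coefficients highest degree first (numpy
    convention).  Requires at least four points with at least four
    distinct column values.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise InsufficientPointsError("need >= 4 (row, col) points")
    rows, cols = pts[:, 0], pts[:, 1]
    if len(np.unique(cols)) < 4:
        raise InsufficientPointsError("need >= 4 distinct column values")
    return np.polyfit(cols, rows, 3)


def build_mask(
    shape: Tuple[int, int],
    curves: Sequence[np.ndarray],
    lateral_bounds: Sequence[Tuple[int, int]],
) -> BreastMask:
    """Mask true above the fitted inframammary curve(s) within bounds.

    Each curve pairs with an inclusive (col_lo, col_hi) lateral span; a
    pixel is kept when it lies in some span with row <= p(col).  Pixels
    strictly below a curve, or outside every span, are removed.
    """
    if len(curves) != len(lateral_bounds):
        raise ValueError("one lateral bound per curve required")
    n_rows, n_cols = shape
    mask = np.zeros(shape, dtype=bool)
    rows = np.arange(n_rows)[:, None]
    for coeffs, (lo, hi) in zip(curves, lateral_bounds):
        lo, hi = max(int(lo), 0), min(int(hi), n_cols - 1)
        if hi < lo:
            continue
        cols = np.arange(lo, hi + 1)
        curve_rows = np.polyval(np.asarray(coeffs, dtype=float), cols)
        mask[:, lo : hi + 1] |= rows <= curve_rows[None, :]
    if not mask.any():
        raise EmptyMaskError("segmentation removed every pixel")
    return BreastMask(mask=mask, curve_coeffs=[np.asarray(c, float) for c in curves])


def locate_hotspot(thermogram: Thermogram, mask: BreastMask) -> Tuple[int, int, float]:
    """Hottest masked pixel; ties go to the smallest row, then column."""
    temps = thermogram.temperatures
    if mask.mask.shape != temps.shape:
        raise ValueError("mask shape must match thermogram")
    masked = np.where(mask.mask, temps, -np.inf)
    flat = int(np.argmax(masked))  # row-major argmax = required tie-break
    r, c = np.unravel_index(flat, temps.shape)
    return int(r), int(c), float(temps[r, c])


_DIRECTIONS = ((-1, 0), (1, 0), (0, -1), (0, 1))  # up, down, left, right


def extract_std_profile(
    thermogram: Thermogram,
    mask: BreastMask,
    hotspot: Tuple[int, int],
    a_max: float = MAX_PROFILE_EXTENT_M,
) -> RoIProfile:
    """Mean radial temperature profile from four axis-aligned rays.

    At offset k (pixels) each ray samples the pixel k steps from the
    hotspot along its axis; a ray that leaves the image or the mask is
    dropped from that offset onward.  The profile truncates at the last
    offset with at least one surviving ray.
    """
    if a_max > MAX_PROFILE_EXTENT_M + 1e-12:
        raise ValueError(f"a_max must be <= {MAX_PROFILE_EXTENT_M} m")
    temps = thermogram.temperatures
    n_rows, n_cols = temps.shape
    r0, c0 = hotspot
    if not mask.mask[r0, c0]:
        raise ValueError("hotspot must lie inside the mask")

    step = thermogram.pixel_size
    k_max = int(round(a_max / step))
    active = list(_DIRECTIONS)
    mean_temp, n_dir = [], []
    for k in range(k_max + 1):
        vals = []
        still = []
        for dr, dc in active:
            r, c = r0 + k * dr, c0 + k * dc
            if 0 <= r < n_rows and 0 <= c < n_cols and mask.mask[r, c]:
                vals.append(temps[r, c])
                still.append((dr, dc))
        active = still
        if not vals:
            break
        mean_temp.append(float(np.mean(vals)))
        n_dir.append(len(vals))

    if len(mean_temp) < 2:
        raise DegenerateProfileError("no valid offset beyond the hotspot")
    offsets = np.arange(len(mean_temp)) * step
    return RoIProfile(
        offsets=offsets,
        mean_temp=np.asarray(mean_temp),
        tmax=float(temps[r0, c0]),
        hotspot=(int(r0), int(c0)),
        te=thermogram.ambient_temp,
        n_directions=np.asarray(n_dir),
    )


def delta_T(thermogram: Thermogram, mask: BreastMask) -> float:
    """Peak-minus-mean masked temperature; >= 2 degC flags abnormality."""
    vals = thermogram.temperatures[mask.mask]
    return float(vals.max() - vals.mean())


def quantize_thermal_levels(
    thermogram: Thermogram, mask: BreastMask, n_levels: int
) -> np.ndarray:
    """Equal-width temperature bins over the masked range (visual aid).

    Returns an integer label matrix, -1 outside the mask.  A degenerate
    range (flat field) yields a single label 0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    temps = thermogram.temperatures
    vals = temps[mask.mask]
    lo, hi = float(vals.min()), float(vals.max())
    labels = np.full(temps.shape, -1, dtype=int)
    if hi == lo:
        labels[mask.mask] = 0
        return labels
    edges = np.linspace(lo, hi, n_levels + 1)
    binned = np.clip(np.digitize(temps, edges[1:-1]), 0, n_levels - 1)
    labels[mask.mask] = binned[mask.mask]
    return labels


def save_profile(profile: RoIProfile, path) -> None:
    """Write a profile as CSV (offset_m, mean_temp_C, n_directions).

    Hotspot and ambient temperature are kept in '#'-prefixed header lines
    so the CSV round-trips through :func:`load_profile`.
    """
    import pandas as pd

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# hotspot_row={profile.hotspot[0]}\n")
        fh.write(f"# hotspot_col={profile.hotspot[1]}\n")
        fh.write(f"# te_C={profile.te!r}\n")
        pd.DataFrame(
            {
                "offset_m": profile.offsets,
                "mean_temp_C": profile.mean_temp,
                "n_directions": profile.n_directions,
            }
        ).to_csv(fh, index=False, float_format="%.17g")


def load_profile(path) -> RoIProfile:
    """Read a profile CSV written by :func:`save_profile`."""
    import pandas as pd

    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return RoIProfile(
        offsets=df["offset_m"].to_numpy(),
        mean_temp=df["mean_temp_C"].to_numpy(),
        tmax=float(df["mean_temp_C"].iloc[0]),
        hotspot=(int(meta.get("hotspot_row", 0)), int(meta.get("hotspot_col", 0))),
        te=float(meta.get("te_C", 22.0)),
        n_directions=df["n_directions"].to_numpy(),
    )
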