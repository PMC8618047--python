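"""Analytical heat-source forward model and synthetic thermogram generation.

A localized metabolic heat source (a warm lesion) buried at depth ``d``
below the skin produces, in the steady-state point-source solution of the
bio-heat balance, a surface temperature

    T(a) = Te + q / (4 pi h0 (d^2 + a^2)),

where ``a`` is the lateral distance on the skin from the point directly
above the source, ``q`` the source intensity (W), ``h0`` the heat-exchange
coefficient with the environment and ``Te`` the ambient temperature.  A
spherical source of radius ``R`` behaves as a point source at effective
depth ``d + R``.

The generator embeds this profile in a 2-D image on a breast-shaped mask,
adds sensor noise, and produces labeled cohorts with known ground truth;
it is the oracle against which the inverse estimators are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd

from .optics import Thermogram
from .segmentation import BreastMask, build_mask, delta_T

__all__ = [
    "HeatSourceTruth",
    "CohortSpec",
    "SingularityError",
    "CohortGenerationError",
    "forward_temperature_point",
    "forward_temperature_sphere",
    "synth_thermogram",
    "synth_cohort",
    "FOUR_PI_H0",
    "DEFAULT_H0",
]

DEFAULT_H0 = 8.77  # W/m^2.degC, skin-environment heat exchange coefficient
FOUR_PI_H0 = 4.0 * np.pi * DEFAULT_H0


class SingularityError(ValueError):
    """Evaluation exactly at a zero-depth point source."""


class CohortGenerationError(RuntimeError):
    """Parameter ranges incompatible with the labeling constraints."""


@dataclass(frozen=True)
class HeatSourceTruth:
    """Ground-truth description of one embedded heat source.

    surface_pos is the (row, col) pixel directly above the source centre;
    depth and radius are in metres, intensity in watts.  radius 0 denotes
    a point source.
    """

    surface_pos: Tuple[int, int]
    depth: float
    intensity: float
    radius: float = 0.0
    te: float = 22.0
    h0: float = DEFAULT_H0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not self.h0 > 0:
            raise ValueError("h0 must be > 0")


def forward_temperature_point(a, src: HeatSourceTruth):
    """Surface temperature at lateral offset(s) ``a`` for a point source.

    Implements Te + q / (4 pi h0 (d^2 + a^2)); at a = 0 this is the peak
    temperature Te + q / (4 pi h0 d^2).
    """
    a = np.asarray(a, dtype=float)
    denom = src.depth**2 + a**2
    if np.any(denom == 0):
        raise SingularityError("zero depth evaluated at a = 0")
    out = src.te + src.intensity / (4.0 * np.pi * src.h0 * denom)
    return float(out) if out.ndim == 0 else out


def forward_temperature_sphere(a, src: HeatSourceTruth):
    """Surface temperature for a spherical source: point source at d + R."""
    if src.depth + src.radius <= 0:
        raise SingularityError("d + R must be > 0 for a spherical source")
    effective = HeatSourceTruth(
        surface_pos=src.surface_pos,
        depth=src.depth + src.radius,
        intensity=src.intensity,
        radius=0.0,
        te=src.te,
        h0=src.h0,
    )
    return forward_temperature_point(a, effective)


def _background_field(
    shape: Tuple[int, int],
    background: "float | np.ndarray | Callable[[np.ndarray, np.ndarray], np.ndarray]",
) -> np.ndarray:
    rows, cols = np.indices(shape)
    if callable(background):
        return np.asarray(background(rows, cols), dtype=float)
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 0:
        return np.full(shape, float(bg))
    if bg.shape != shape:
        raise ValueError("background array shape must match image shape")
    return bg


def synth_thermogram(
    truth: HeatSourceTruth,
    background: "float | np.ndarray | Callable" = 32.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    shape: Tuple[int, int] = (480, 640),
    pixel_size: float = 0.0006,
    mask: Optional[np.ndarray] = None,
) -> Thermogram:
    """Embed one heat source in a 2-D background and add sensor noise.

    Pixel (i, j) receives background(i, j) plus the point-source (or, when
    truth.radius > 0, spherical-source) increment at the Euclidean pixel
    distance from ``truth.surface_pos`` scaled by ``pixel_size``, plus
    Gaussian noise of standard deviation ``noise_sd`` drawn from ``seed``.
    The label is assigned from the peak-minus-mean criterion: >= 2 degC
    marks the thermogram abnormal.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    r0, c0 = truth.surface_pos
    if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
        raise ValueError("surface_pos outside image")

    rows, cols = np.indices(shape)
    dist = np.hypot(rows - r0, cols - c0) * pixel_size
    forward = forward_temperature_sphere if truth.radius > 0 else forward_temperature_point
    increment = forward(dist, truth) - truth.te

    temps = _background_field(shape, background) + increment
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temps = temps + rng.normal(0.0, noise_sd, size=shape)

    sel = np.ones(shape, dtype=bool) if mask is None else mask
    masked = temps[sel]
    label = "abnormal" if masked.max() - masked.mean() >= 2.0 else "normal"
    return Thermogram(temperatures=temps, pixel_size=pixel_size, ambient_temp=truth.te, label=label)


@dataclass
class CohortSpec:
    """Specification of a synthetic screening cohort.

    Each member gets a flat per-subject baseline skin temperature drawn
    from ``background_range`` (optionally with a smooth ramp), one embedded
    source with depth from the class depth range and intensity induced by a
    peak skin-temperature elevation drawn from the class elevation range
    (q = elevation * 4 pi h0 d^2, so peak temperatures stay physiological),
    and additive sensor noise.  Class-disjoint depth ranges make the cohort
    separable in the recovered-parameter space by construction.

    The defaults emulate the study conditions: 49 normal / 38 abnormal,
    0.04 degC sensor noise, 22 degC ambient, 0.6 mm pixels, and abnormal
    members whose peak elevation guarantees delta-T >= 2 degC.
    """

    n_normal: int = 49
    n_abnormal: int = 38
    background_range: Tuple[float, float] = (30.0, 34.0)
    normal_depth_range: Tuple[float, float] = (0.010, 0.015)
    normal_elevation_range: Tuple[float, float] = (0.5, 1.2)
    abnormal_depth_range: Tuple[float, float] = (0.004, 0.008)
    abnormal_elevation_range: Tuple[float, float] = (2.5, 5.0)
    noise_sd: float = 0.04
    seed: int = 0
    shape: Tuple[int, int] = (120, 120)
    pixel_size: float = 0.0006
    te: float = 22.0
    h0: float = DEFAULT_H0
    background_ramp: float = 0.0  # degC end-to-end vertical gradient
    mask_geometry: str = "curve"  # 'curve' masks below an inframammary fold
    source_margin_px: int = 40
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mask_geometry not in ("none", "curve"):
            raise ValueError("mask_geometry must be 'none' or 'curve'")


def _cohort_mask(spec: CohortSpec) -> BreastMask:
    n_rows, n_cols = spec.shape
    if spec.mask_geometry == "none":
        coeffs = np.array([0.0, 0.0, 0.0, float(n_rows)])  # fold below the frame
        return build_mask(spec.shape, [coeffs], [(0, n_cols - 1)])
    # Gentle cubic inframammary fold near the bottom of the frame.
    fold_row = n_rows - 8
    amp = 4.0
    c_mid = (n_cols - 1) / 2.0
    # row = fold_row - amp * cos-ish bowl via cubic through three anchor cols
    cols = np.array([0.0, c_mid, n_cols - 1.0, n_cols / 4.0])
    rows = np.array([fold_row - amp, fold_row, fold_row - amp, fold_row - amp / 2.0])
    coeffs = np.polyfit(cols, rows, 3)
    return build_mask(spec.shape, [coeffs], [(0, n_cols - 1)])


def synth_cohort(spec: CohortSpec):
    """Generate a labeled cohort of synthetic thermograms with ground truth.

    Returns (thermograms, mask, truth_table).  Every abnormal member
    satisfies delta-T >= 2 degC and every normal member delta-T < 2 degC;
    members violating their label's constraint are resampled up to
    ``spec.max_retries`` times before a CohortGenerationError is raised.
    The truth table records id, label, depth, intensity, source position
    and the realized delta-T.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _cohort_mask(spec)
    n_rows, n_cols = spec.shape
    m = spec.source_margin_px
    if n_rows - 2 * m <= 0 or n_cols - 2 * m <= 0:
        raise ValueError("source_margin_px too large for image shape")

    thermograms = []
    records = []
    four_pi_h0 = 4.0 * np.pi * spec.h0

    def one_member(idx: int, label: str) -> None:
        if label == "normal":
            d_range, e_range = spec.normal_depth_range, spec.normal_elevation_range
            ok = lambda dt: dt < 2.0
        else:
            d_range, e_range = spec.abnormal_depth_range, spec.abnormal_elevation_range
            ok = lambda dt: dt >= 2.0
        for _ in range(spec.max_retries):
            d = rng.uniform(*d_range)
            elev = rng.uniform(*e_range)
            q = elev * four_pi_h0 * d**2
            r0 = int(rng.integers(m, n_rows - m))
            c0 = int(rng.integers(m, n_cols - m))
            bg0 = rng.uniform(*spec.background_range)
            if spec.background_ramp != 0.0:
                ramp = spec.background_ramp
                background = lambda rows, cols: bg0 + ramp * rows / max(n_rows - 1, 1)
            else:
                background = bg0
            truth = HeatSourceTruth((r0, c0), d, q, 0.0, spec.te, spec.h0)
            tg = synth_thermogram(
                truth,
                background=background,
                noise_sd=spec.noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                shape=spec.shape,
                pixel_size=spec.pixel_size,
                mask=mask.mask,
            )
            dt = delta_T(tg, mask)
            if ok(dt):
                tg.label = label
                thermograms.append(tg)
                records.append(
                    dict(id=f"t{idx:03d}", label=label, d_m=d, q_W=q,
                         row=r0, col=c0, delta_T=dt)
                )
                return
        raise CohortGenerationError(
            f"could not satisfy the delta-T constraint for a {label} member "
            f"after {spec.max_retries} retries"
        )

    idx = 0
    for _ in range(spec.n_normal):
        one_member(idx, "normal")
        idx += 1
    for _ in range(spec.n_abnormal):
        one_member(idx, "abnormal")
        idx += 1

    truth_table = pd.DataFrame.from_records(
        records, columns=["id", "label", "d_m", "q_W", "row", "col", "delta_T"]
    )
    return thermograms, mask, truth_table
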