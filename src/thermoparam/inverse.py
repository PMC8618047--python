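"""Inverse estimation of heat-source parameters from a radial profile.

Two routes recover the depth ``d`` and intensity ``q`` of the buried
source from the surface temperature distribution T(a):

*Closed-form (D-I-R) inversion.*  Solving the point-source forward model
for the unknowns at a single offset ``a`` gives

    d(a) = a * sqrt((T(a) - Te) / (Tmax - T(a))),
    q(a) = 4 pi h0 a^2 (T(a) - Te)(Tmax - Te) / (Tmax - T(a)),

and an equivalent source radius R = cbrt(q / (Qm At)) from the metabolic
heat rate Qm of active tissue.  On a noiseless model profile these are
exact at every offset.

*Lorentz-curve fitting.*  The whole profile is fit by least squares to
y = A / (a^2 + w^2) + y0, which is the same functional form; the depth is
d = |w| and, with the 4 pi h0 = 1 unit convention, the intensity is
q = A.  The fit quality is summarized by the coefficient of
determination R^2.

Either route, evaluated at an offset ``a``, yields the five-component
pattern vector {Tmax, d, q, R, theta} used for classification, where
theta = arctan(q / a) in degrees summarizes the intensity-to-position
ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .segmentation import RoIProfile

__all__ = [
    "ModelConstants",
    "HeatSourceParams",
    "LorentzFit",
    "SingularInversionError",
    "FitFailureError",
    "dir_depth",
    "dir_intensity",
    "source_radius",
    "theta_angle",
    "lorentz_fit",
    "lorentz_params",
    "r_squared",
    "pattern_vector",
    "DEFAULT_CONSTANTS",
]


class SingularInversionError(ValueError):
    """Inversion at T(a) >= Tmax or T(a) < Te, where the model is undefined."""


class FitFailureError(RuntimeError):
    """Lorentz least squares failed to converge or the profile is flat."""

    def __init__(self, message: str, last_residual: Optional[float] = None):
        super().__init__(message)
        self.last_residual = last_residual


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants of the bio-heat inversion.

    h0 : skin-environment heat exchange coefficient, W/m^2.degC.
    qm : metabolic heat rate of active tissue, W/m^3.
    at : cell-volume constant in the radius relation (dimensionless here;
         only the monotone q -> R mapping matters for classification).
    te : ambient temperature, degC.
    radius_convention : 'ratio' uses R = cbrt(q/(qm*at)); 'sphere' uses the
         sphere-volume form R = cbrt(3q/(4 pi qm)).
    """

    h0: float = 8.77
    qm: float = 418.6
    at: float = 1.0
    te: float = 22.0
    radius_convention: str = "ratio"

    def __post_init__(self) -> None:
        if not (self.h0 > 0 and self.qm > 0 and self.at > 0):
            raise ValueError("h0, qm, at must all be > 0")
        if self.radius_convention not in ("ratio", "sphere"):
            raise ValueError("radius_convention must be 'ratio' or 'sphere'")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class HeatSourceParams:
    """One extraction result: the pattern vector plus provenance.

    tmax (degC), depth d (m), intensity q (W for the closed-form route;
    Lorentz-convention units, 4 pi h0 = 1, for the fitting route), radius
    (model units), theta (degrees), tagged with the method and the offset
    ``a`` at which the vector was evaluated.  fit_r_squared measures how
    well the recovered model reproduces the observed profile.
    """

    tmax: float
    depth: float
    intensity: float
    radius: float
    theta: float
    method: str
    a: float
    fit_r_squared: Optional[float] = None

    def as_features(self) -> np.ndarray:
        return np.array([self.tmax, self.depth, self.intensity, self.radius, self.theta])


@dataclass(frozen=True)
class LorentzFit:
    """Converged Lorentz least-squares fit A/(a^2+w^2)+y0 with its R^2."""

    amplitude: float
    width: float
    offset: float
    fit_r_squared: float


def dir_depth(t_a: float, tmax: float, te: float, a: float) -> float:
    """Closed-form source depth from one profile sample.

    d = a * sqrt((T(a) - Te) / (Tmax - T(a))).  A sample at the ambient
    temperature carries no signal and returns depth 0 with a warning.
    """
    if a <= 0:
        raise ValueError("offset a must be > 0")
    if t_a < te:
        raise SingularInversionError("T(a) below ambient temperature")
    if t_a >= tmax:
        raise SingularInversionError("T(a) must be strictly below Tmax")
    if t_a == te:
        warnings.warn("flat profile: T(a) equals ambient, depth undefined, returning 0")
        return 0.0
    return a * math.sqrt((t_a - te) / (tmax - t_a))


def dir_intensity(t_a: float, tmax: float, te: float, a: float, h0: float) -> float:
    """Closed-form source intensity from one profile sample, in watts.

    q = 4 pi h0 a^2 (T(a) - Te)(Tmax - Te) / (Tmax - T(a)); equivalently
    4 pi h0 d^2 (Tmax - Te) with the depth from ``dir_depth``.
    """
    if a <= 0:
        raise ValueError("offset a must be > 0")
    if h0 <= 0:
        raise ValueError("h0 must be > 0")
    if t_a < te:
        raise SingularInversionError("T(a) below ambient temperature")
    if t_a >= tmax:
        raise SingularInversionError("T(a) must be strictly below Tmax")
    if t_a == te:
        warnings.warn("flat profile: T(a) equals ambient, intensity 0")
        return 0.0
    return 4.0 * math.pi * h0 * a**2 * (t_a - te) * (tmax - te) / (tmax - t_a)


def source_radius(q: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Equivalent source radius from the intensity.

    The default convention is the direct ratio R = cbrt(q / (Qm At)); the
    sphere-volume convention cbrt(3 q / (4 pi Qm)) is selectable on the
    constants.  Either is a strictly increasing map of q, which is all the
    classifier relies on.
    """
    if q < 0:
        raise ValueError("intensity q must be >= 0")
    if constants.radius_convention == "sphere":
        return float(np.cbrt(3.0 * q / (4.0 * math.pi * constants.qm)))
    return float(np.cbrt(q / (constants.qm * constants.at)))


def theta_angle(q: float, a: float) -> float:
    """Inclination of the intensity-position ratio, arctan(q/a) in degrees.

    The numeric ratio q/a is taken literally in the method's own units
    (q in W or Lorentz units, a in metres).  At a = 0 the angle saturates:
    90 degrees for a positive intensity, 0 for none.
    """
    if a < 0:
        raise ValueError("offset a must be >= 0")
    if a == 0:
        return 90.0 if q > 0 else 0.0
    return math.degrees(math.atan(q / a))


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.size < 2:
        raise ValueError("observed and fitted must be equal-length vectors, n >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for a constant observed vector")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def _lorentz(a: np.ndarray, amplitude: float, width: float, offset: float) -> np.ndarray:
    return amplitude / (a**2 + width**2) + offset


def lorentz_fit(
    profile: RoIProfile,
    max_nfev: int = 1000,
    tol: float = 1e-12,
) -> LorentzFit:
    """Least-squares Lorentz fit of the whole radial profile.

    Initial values: the baseline starts at the profile minimum, the width
    at the half-prominence offset, and the amplitude at the value that
    reproduces the observed peak.  The width is reported positive (it only
    enters squared).  Non-convergence, or a profile too flat to carry a
    peak, raises FitFailureError with the last residual attached.
    """
    a = profile.offsets
    y = profile.mean_temp
    if len(a) < 4:
        raise ValueError("need >= 4 profile samples to fit 3 parameters")

    y0_init = float(y.min())
    prominence = float(profile.tmax - y0_init)
    if prominence <= 0.0:
        raise FitFailureError("flat profile: no peak to fit", last_residual=0.0)
    half = y0_init + prominence / 2.0
    below = np.nonzero(y <= half)[0]
    w_init = float(a[below[0]]) if len(below) and a[below[0]] > 0 else float(a[-1])
    amp_init = prominence * w_init**2

    try:
        popt, _ = curve_fit(
            _lorentz,
            a,
            y,
            p0=(amp_init, w_init, y0_init),
            maxfev=max_nfev,
            ftol=tol,
            xtol=tol,
            gtol=tol,
        )
    except RuntimeError as exc:
        resid = float(np.sum((y - _lorentz(a, amp_init, w_init, y0_init)) ** 2))
        raise FitFailureError(f"Lorentz fit did not converge: {exc}", resid) from exc

    amplitude, width, offset = float(popt[0]), abs(float(popt[1])), float(popt[2])
    rsq = r_squared(y, _lorentz(a, amplitude, width, offset))
    return LorentzFit(amplitude=amplitude, width=width, offset=offset, fit_r_squared=rsq)


def lorentz_params(amplitude: float, width: float) -> Tuple[float, float]:
    """Depth and intensity under the Lorentz convention: d = |w|, q = A."""
    return abs(width), amplitude


def pattern_vector(
    profile: RoIProfile,
    method: str,
    a: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> HeatSourceParams:
    """Assemble the five-feature pattern vector {Tmax, d, q, R, theta} at ``a``.

    method='dir' inverts the closed forms at the single profile sample
    T(a); method='lorentz' fits the whole profile once (so d and q do not
    depend on a) while Tmax and theta(a) carry the positional dependence.
    The offset must lie on the profile grid: no interpolation is done.
    For both methods fit_r_squared compares the profile reconstructed from
    the recovered parameters with the observed one.
    """
    if method not in ("dir", "lorentz"):
        raise ValueError("method must be 'dir' or 'lorentz'")
    if not a > 0:
        raise ValueError("offset a must be > 0")
    k = profile.index_of(a)
    te = profile.te
    tmax = profile.tmax

    if method == "dir":
        t_a = float(profile.mean_temp[k])
        d = dir_depth(t_a, tmax, te, a)
        q = dir_intensity(t_a, tmax, te, a, constants.h0)
        reconstructed = te + q / (4.0 * math.pi * constants.h0 * (d**2 + profile.offsets**2))
        try:
            rsq = r_squared(profile.mean_temp, reconstructed)
        except ValueError:
            rsq = None
    else:
        fit = lorentz_fit(profile)
        d, q = lorentz_params(fit.amplitude, fit.width)
        rsq = fit.fit_r_squared

    return HeatSourceParams(
        tmax=tmax,
        depth=d,
        intensity=q,
        radius=source_radius(max(q, 0.0), constants),
        theta=theta_angle(q, a),
        method=method,
        a=a,
        fit_r_squared=rsq,
    )
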