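"""Rudiment volume from per-section areas via curve fitting.

The epithelial cross-section area is measured on every consecutive section
through a rudiment and plotted against cumulative section depth.  Because
individual sections are occasionally lost during histology, the area-depth
profile is fitted with Levenberg–Marquardt nonlinear least squares and the
volume taken as the area under the fitted curve — the fit bridges the gaps
that direct numerical integration cannot.

Two dome-shaped models are available:

``gaussian``
    ``A * exp(-(z - z0)^2 / (2 s^2))``; volume ``A |s| sqrt(2 pi)``.
``parabolic``
    ``max(0, k (R^2 - (z - z0)^2))``, the exact profile of a sphere or
    ellipsoid of revolution; volume ``4/3 k R^3``.

Depths use nominal cumulative thickness (index x section thickness); lost
sections leave gaps without renumbering.  :func:`trapezoid_volume` provides
the model-free baseline on complete stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from mamrud.errors import FitConvergenceError, ValidationError

__all__ = [
    "AreaProfile",
    "VolumeEstimate",
    "build_profile",
    "fit_profile",
    "trapezoid_volume",
    "MODELS",
]


@dataclass(frozen=True)
class AreaProfile:
    """(cumulative depth um, area um^2) samples of one rudiment."""

    depths_um: np.ndarray
    areas_um2: np.ndarray
    section_thickness_um: float
    lost_depths_um: tuple[float, ...] = ()

    def __post_init__(self):
        depths = np.asarray(self.depths_um, dtype=float)
        areas = np.asarray(self.areas_um2, dtype=float)
        if depths.shape != areas.shape or depths.ndim != 1:
            raise ValidationError("depths and areas must be matching 1-D arrays", field="depths_um")
        if not np.all(np.diff(depths) > 0):
            raise ValidationError("depths must be strictly increasing", field="depths_um")
        if np.any(areas < 0):
            raise ValidationError("areas must be >= 0", field="areas_um2")
        object.__setattr__(self, "depths_um", depths)
        object.__setattr__(self, "areas_um2", areas)


@dataclass(frozen=True)
class VolumeEstimate:
    """Fitted model, parameters and the area-under-curve volume."""

    model: str
    params: dict
    volume_um3: float
    rms_residual_um2: float
    n_samples: int


def build_profile(
    areas_um2,
    section_thickness_um: float,
    lost=None,
) -> AreaProfile:
    """Assemble an area-depth profile from per-section measurements.

    ``areas_um2[i]`` belongs to nominal section *i* at depth
    ``i * section_thickness_um``; entries flagged in ``lost`` (boolean
    sequence or index list) are dropped, leaving depth gaps.  At least three
    surviving sections are required for the three-parameter fits.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if np.any(areas < 0):
        raise ValidationError("areas must be >= 0", field="areas_um2")
    if section_thickness_um <= 0:
        raise ValidationError("must be > 0", field="section_thickness_um")
    n = areas.size
    lost_mask = np.zeros(n, dtype=bool)
    if lost is not None:
        lost = np.asarray(lost)
        if lost.dtype == bool:
            if lost.size != n:
                raise ValidationError("boolean lost flags must match areas", field="lost")
            lost_mask = lost
        else:
            lost_mask[lost.astype(int)] = True
    keep = ~lost_mask
    if keep.sum() < 3:
        raise ValidationError("need >= 3 non-lost sections for a determined fit", field="areas_um2")
    depths = np.arange(n) * section_thickness_um
    return AreaProfile(
        depths_um=depths[keep],
        areas_um2=areas[keep],
        section_thickness_um=section_thickness_um,
        lost_depths_um=tuple(depths[lost_mask]),
    )


def _gaussian(z, amplitude, z0, sigma):
    return amplitude * np.exp(-((z - z0) ** 2) / (2.0 * sigma**2))


def _gaussian_volume(amplitude, z0, sigma):
    return abs(amplitude) * abs(sigma) * np.sqrt(2.0 * np.pi)


def _parabolic(z, k, z0, radius):
    return np.maximum(0.0, k * (radius**2 - (z - z0) ** 2))


def _parabolic_volume(k, z0, radius):
    return max(0.0, k) * 4.0 / 3.0 * abs(radius) ** 3


MODELS = {
    "gaussian": (_gaussian, _gaussian_volume, ("amplitude", "z0", "sigma")),
    "parabolic": (_parabolic, _parabolic_volume, ("k", "z0", "radius")),
}


def _initial_guess(model: str, depths: np.ndarray, areas: np.ndarray):
    z0 = depths[np.argmax(areas)]
    span = max(depths[-1] - depths[0], 1.0)
    if model == "gaussian":
        return [areas.max(), z0, span / 4.0]
    radius = span / 2.0
    return [areas.max() / radius**2, z0, radius]


def fit_profile(
    profile: AreaProfile,
    model: str = "gaussian",
    max_iter: int = 500,
    xtol: float = 1e-8,
) -> VolumeEstimate:
    """Levenberg–Marquardt fit of a dome model; volume under the curve.

    The fit converges when the relative parameter change drops below
    ``xtol`` or errors out after ``max_iter`` function evaluations, carrying
    the last residual.  An all-zero profile yields volume 0 without fitting;
    a profile with fewer than three positive samples is degenerate (the
    three-parameter dome is unconstrained) and raises
    :class:`FitConvergenceError`.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; choose from {sorted(MODELS)}", field="model")
    func, volume_of, names = MODELS[model]
    depths, areas = profile.depths_um, profile.areas_um2

    if np.all(areas == 0):
        return VolumeEstimate(model, dict.fromkeys(names, 0.0), 0.0, 0.0, areas.size)
    if np.count_nonzero(areas > 0) < 3:
        resid = float(np.sqrt(np.mean(areas**2)))
        raise FitConvergenceError(
            "fewer than 3 positive areas: dome fit is under-determined", last_residual=resid
        )

    p0 = _initial_guess(model, depths, areas)
    try:
        popt, _ = optimize.curve_fit(
            func, depths, areas, p0=p0, method="lm", maxfev=max_iter, xtol=xtol
        )
    except RuntimeError as exc:
        resid = float(np.sqrt(np.mean((func(depths, *p0) - areas) ** 2)))
        raise FitConvergenceError(str(exc), last_residual=resid) from exc
    if not np.all(np.isfinite(popt)):
        raise FitConvergenceError("fit diverged to non-finite parameters")

    fitted = func(depths, *popt)
    rms = float(np.sqrt(np.mean((fitted - areas) ** 2)))
    return VolumeEstimate(
        model=model,
        params=dict(zip(names, (float(v) for v in popt))),
        volume_um3=float(volume_of(*popt)),
        rms_residual_um2=rms,
        n_samples=int(areas.size),
    )


def trapezoid_volume(profile: AreaProfile) -> float:
    """Model-free trapezoidal integration of a complete profile.

    Serves as the independent baseline for the curve fits; undefined when
    sections are missing, since the raw samples then under-cover the shape.
    """
    if profile.lost_depths_um:
        raise ValidationError("trapezoid baseline undefined with lost sections", field="profile")
    return float(np.trapezoid(profile.areas_um2, profile.depths_um))
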