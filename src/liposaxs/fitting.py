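"""Least-squares shell-model fitting of scattering curves.

The model curve is ``scale * I_poly(q; profile, dist)``.  Residuals are taken
in log-intensity because vesicle curves span several decades and both the
low-q shoulder and the mid-q wall features must be matched; they are
uncertainty-weighted when the curve carries sigmas.  Optimization is bounded
local least squares (scipy ``least_squares``, trust-region reflective) from a
caller-supplied starting model — the procedure is a local refinement of a
physically motivated profile, not a global search — and is deterministic for
a fixed start.

Goodness of fit is reported as the reliability factor

    R = sum_q |I_obs(q) - I_model(q)| / sum_q I_obs(q)

over the fitted q range (default q <= 0.2 Å^-1; above that the spherical
shell idealization, not the data, dominates the residual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import RegridRequiredError
from .shell_model import (
    ScatteringCurve,
    ShellProfile,
    SizeDistribution,
    intensity_polydisperse,
)

__all__ = [
    "FitResult",
    "reliability_factor",
    "fit_shell_model",
    "size_distribution_from_fit",
    "parameter_names",
]

DEFAULT_FIT_QMAX = 0.2  # Å^-1


def reliability_factor(
    observed: ScatteringCurve,
    model: ScatteringCurve,
    q_max: float | None = None,
) -> float:
    """R = sum |I_obs - I_model| / sum I_obs on a shared q grid."""
    if len(observed.q) != len(model.q) or not np.allclose(observed.q, model.q):
        raise RegridRequiredError("observed and model curves must share a q grid")
    sel = slice(None) if q_max is None else observed.q <= q_max
    i_obs = observed.intensity[sel]
    i_mod = model.intensity[sel]
    return float(np.sum(np.abs(i_obs - i_mod)) / np.sum(i_obs))


def parameter_names(profile: ShellProfile) -> list[str]:
    """Ordered free-parameter names for a profile of n shells.

    ``scale`` (global, log10), ``contrast_i`` for each region (1 = water
    pool), ``thickness_i`` for each wall region i >= 2, ``mean_radius`` and
    ``sigma`` of the size distribution.
    """
    n = profile.n
    return (
        ["scale"]
        + [f"contrast_{i}" for i in range(1, n + 1)]
        + [f"thickness_{i}" for i in range(2, n + 1)]
        + ["mean_radius", "sigma"]
    )


@dataclass
class FitResult:
    """Converged (or best-so-far) shell-model fit."""

    profile: ShellProfile
    distribution: SizeDistribution
    scale: float
    reliability_r: float
    params: dict[str, float]
    free: tuple[str, ...]
    bounds_hit: dict[str, bool]
    cost_initial: float
    cost_final: float
    success: bool
    message: str


def _expand_free(free, names) -> list[str]:
    out: list[str] = []
    for f in free:
        if f == "contrasts":
            out.extend(n for n in names if n.startswith("contrast_"))
        elif f == "thicknesses":
            out.extend(n for n in names if n.startswith("thickness_"))
        elif f in names:
            out.append(f)
        else:
            raise ValueError(f"unknown free parameter {f!r}")
    return list(dict.fromkeys(out))


_DEFAULT_BOUNDS = {
    "scale": (-12.0, 12.0),  # log10 units
    "contrast": (-10.0, 10.0),
    "thickness": (1.0, 200.0),
    "mean_radius": (50.0, 5000.0),
    "sigma": (0.0, 2000.0),
}


def _default_bound(name: str) -> tuple[float, float]:
    key = name.split("_")[0] if name[-1].isdigit() else name
    return _DEFAULT_BOUNDS[key]


def _pack(profile: ShellProfile, dist: SizeDistribution, scale: float) -> dict[str, float]:
    vals = {"scale": float(np.log10(scale))}
    for i, c in enumerate(profile.contrasts, start=1):
        vals[f"contrast_{i}"] = float(c)
    thick = profile.thicknesses
    for i in range(2, profile.n + 1):
        vals[f"thickness_{i}"] = float(thick[i - 1])
    vals["mean_radius"] = float(dist.mean_radius)
    vals["sigma"] = float(dist.sigma)
    return vals


def _unpack(
    vals: dict[str, float], base_profile: ShellProfile, base_dist: SizeDistribution
) -> tuple[ShellProfile, SizeDistribution, float]:
    n = base_profile.n
    contrasts = [vals[f"contrast_{i}"] for i in range(1, n + 1)]
    thick = [vals[f"thickness_{i}"] for i in range(2, n + 1)]
    wall = float(np.sum(thick))
    mean = vals["mean_radius"]
    # rebuild boundaries outermost-in at the mean overall radius
    radii = mean - np.concatenate([[wall], wall - np.cumsum(thick)])
    profile = ShellProfile(
        tuple(
            type(s)(outer_semi_axis=float(r), contrast=float(c), axial_ratio=s.axial_ratio)
            for s, r, c in zip(base_profile.shells, radii, contrasts)
        )
    )
    r_min = max(base_dist.r_min, wall)
    dist = SizeDistribution(mean_radius=mean, sigma=vals["sigma"], r_min=r_min)
    return profile, dist, 10.0 ** vals["scale"]


def fit_shell_model(
    curve: ScatteringCurve,
    profile: ShellProfile,
    dist: SizeDistribution,
    free: tuple[str, ...] = ("scale", "contrasts"),
    bounds: dict[str, tuple[float, float]] | None = None,
    q_max: float = DEFAULT_FIT_QMAX,
    n_radius: int = 151,
    scale0: float | None = None,
    max_nfev: int = 2000,
) -> FitResult:
    """Refine shell contrasts/thicknesses and size distribution against data.

    Parameters named in ``free`` (see :func:`parameter_names`; the shorthands
    ``"contrasts"`` and ``"thicknesses"`` expand per shell) are optimized
    inside box bounds; everything else is held at the starting model.  With
    an empty ``free`` the fit is a no-op and only the reliability factor of
    the starting model is evaluated.
    """
    names = parameter_names(profile)
    free_names = _expand_free(free, names)
    bounds = bounds or {}

    sel = curve.q <= q_max
    q_fit = curve.q[sel]
    i_obs = curve.intensity[sel]
    if np.any(i_obs <= 0):
        raise ValueError("nonpositive intensities in the fit range; cannot take log residuals")
    ln_obs = np.log(i_obs)
    if curve.sigma is not None and np.all(curve.sigma[sel] > 0):
        w = i_obs / curve.sigma[sel]  # d ln I = dI / I
        w = w / np.mean(w)
    else:
        w = np.ones_like(q_fit)

    def model_intensity(prof, dst):
        return intensity_polydisperse(prof, dst, q_fit, n_radius=n_radius)

    if scale0 is None:
        i_start = model_intensity(profile, dist)
        scale0 = float(np.exp(np.mean(ln_obs - np.log(i_start))))
    vals0 = _pack(profile, dist, scale0)

    def residuals(x):
        vals = dict(vals0)
        vals.update(zip(free_names, x))
        prof, dst, scale = _unpack(vals, profile, dist)
        model = scale * model_intensity(prof, dst)
        return w * (np.log(np.maximum(model, 1e-300)) - ln_obs)

    if free_names:
        x0 = np.array([vals0[nm] for nm in free_names])
        lo = np.array([bounds.get(nm, _default_bound(nm))[0] for nm in free_names])
        hi = np.array([bounds.get(nm, _default_bound(nm))[1] for nm in free_names])
        x0 = np.clip(x0, lo, hi)
        cost0 = 0.5 * float(np.sum(residuals(x0) ** 2))
        res = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac", max_nfev=max_nfev
        )
        if not res.success:
            warnings.warn(
                f"shell-model fit did not converge: {res.message}; returning best-so-far",
                stacklevel=2,
            )
        vals = dict(vals0)
        vals.update(zip(free_names, res.x))
        bounds_hit = {
            nm: bool(np.isclose(xv, l) or np.isclose(xv, h))
            for nm, xv, l, h in zip(free_names, res.x, lo, hi)
        }
        cost1, success, message = float(res.cost), bool(res.success), str(res.message)
    else:
        vals = vals0
        cost0 = cost1 = 0.5 * float(np.sum(residuals(np.empty(0)) ** 2))
        bounds_hit, success, message = {}, True, "no free parameters; evaluation only"

    prof_fit, dist_fit, scale_fit = _unpack(vals, profile, dist)
    model_curve = ScatteringCurve(q=q_fit, intensity=scale_fit * model_intensity(prof_fit, dist_fit))
    observed = ScatteringCurve(q=q_fit, intensity=i_obs)
    r_factor = reliability_factor(observed, model_curve)
    return FitResult(
        profile=prof_fit,
        distribution=dist_fit,
        scale=scale_fit,
        reliability_r=r_factor,
        params={nm: float(vals[nm]) for nm in names},
        free=tuple(free_names),
        bounds_hit=bounds_hit,
        cost_initial=cost0,
        cost_final=cost1,
        success=success,
        message=message,
    )


def size_distribution_from_fit(result: FitResult) -> SizeDistribution:
    """The fitted truncated-Gaussian size distribution."""
    return result.distribution
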