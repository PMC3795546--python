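"""Real-space and Guinier analyses of scattering curves.

The distance distribution function is the direct sine transform of the
intensity,

    p(r) = (r / 2 pi^2) integral_0^{q_max} q I(q) sin(q r) dq ,

evaluated by trapezoidal quadrature on the curve's own q grid.  Because the
data truncate the integral at q_max, a cosine taper over the last decade of
q is applied by default to suppress truncation ripples, which otherwise
contaminate the sub-bilayer region where the intra-wall oscillation lives.

The Guinier radius of gyration comes from a weighted linear regression of
ln I on q^2 over the largest low-q window satisfying q * Rg <= qrg_max,
iterated to self-consistency in Rg.  The default window bound is
q * Rg <= 0.5, much tighter than the classic 1.3: vesicles are large and
their curves bend away from the Guinier law early, and for a homogeneous
sphere the truncation bias of a window reaching q * Rg = 1 is already ~1 %
of Rg, more than this analysis tolerates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AliasingError, NoGuinierRegimeError
from .shell_model import ScatteringCurve

__all__ = [
    "DistanceDistribution",
    "GuinierResult",
    "distance_distribution",
    "intensity_from_distance_distribution",
    "guinier_fit",
    "ripple_extent",
]


@dataclass
class DistanceDistribution:
    """p(r) on an r grid with its detected peak and ripple features."""

    r: np.ndarray
    p: np.ndarray
    peak_position: float = 0.0
    ripple_extent: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)


@dataclass
class GuinierResult:
    """Result of an iterated Guinier fit."""

    rg: float
    i0: float
    fit_q_range: tuple[float, float]
    rg_stderr: float
    n_points: int


def _taper_window(q: np.ndarray) -> np.ndarray:
    """Half-cosine roll-off over the last decade of the q range."""
    q_max = q[-1]
    q0 = q_max / 10.0
    w = np.ones_like(q)
    tail = q > q0
    w[tail] = 0.5 * (1.0 + np.cos(np.pi * (q[tail] - q0) / (q_max - q0)))
    return w


def _refine_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """3-point parabolic refinement of a discrete maximum."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(x[i] + delta * (x[i + 1] - x[i]))


def _zero_extrapolation(q: np.ndarray, intensity: np.ndarray):
    """Guinier extension of the curve from its lowest q toward q = 0.

    Fits ln I on q^2 over the lowest points (q <= 1.6 q_min, at least 5 and
    at most 20 of them) and fills [~q_min/20, q_min) with the fitted
    exponential.  Returns empty arrays when the low-q slope is nonnegative.
    """
    n = int(np.clip(np.searchsorted(q, 1.6 * q[0]), 5, 20))
    if len(q) < n:
        return np.empty(0), np.empty(0)
    slope, intercept = np.polyfit(q[:n] ** 2, np.log(np.maximum(intensity[:n], 1e-300)), 1)
    if slope >= 0:
        return np.empty(0), np.empty(0)
    q_ext = np.linspace(q[0] / 20.0, q[0], 20, endpoint=False)
    return q_ext, np.exp(intercept + slope * q_ext**2)


def distance_distribution(
    curve: ScatteringCurve,
    r_grid: np.ndarray | None = None,
    window: bool = True,
    extrapolate: bool = True,
) -> DistanceDistribution:
    """Distance distribution p(r) by direct sine transform of the curve.

    Parameters
    ----------
    curve:
        Scattering curve; the q grid must be dense enough that
        max(dq) * max(r) < pi, otherwise an :class:`AliasingError` is raised.
    r_grid:
        Distances (Å) to evaluate on.  Defaults to a uniform grid from 0 up
        to the Nyquist distance pi / max(dq).
    window:
        Apply the cosine taper over the last decade of q (default on).
    extrapolate:
        Extend the integrand toward q = 0 with a Guinier fit to the lowest
        points (default on).  For particles whose maximum dimension is not
        tiny compared with 1/q_min, the missing [0, q_min) segment otherwise
        injects long-period truncation oscillations that can swamp the broad
        structural peak.  Note the extension makes the transform nonlinear
        in the intensity; disable it for strict-linearity use.
    """
    q, intensity = curve.q, curve.intensity
    if extrapolate:
        q_ext, i_ext = _zero_extrapolation(q, intensity)
        q = np.concatenate([q_ext, q])
        intensity = np.concatenate([i_ext, intensity])
    dq_max = float(np.max(np.diff(q)))
    if r_grid is None:
        r_grid = np.linspace(0.0, np.pi / dq_max, 1500)
    else:
        r_grid = np.asarray(r_grid, dtype=float)
        if np.any(r_grid < 0):
            raise ValueError("r grid must be nonnegative")
    if dq_max * float(np.max(r_grid)) > np.pi:
        raise AliasingError(
            f"q grid too sparse: max(dq) * r_max = {dq_max * float(np.max(r_grid)):.3f} > pi"
        )

    weighted = q * intensity * (_taper_window(q) if window else 1.0)
    # p(r) = (r / 2 pi^2) ∫ q I(q) sin(qr) dq, trapezoid on the data grid
    sin_qr = np.sin(np.outer(r_grid, q))
    p = r_grid / (2.0 * np.pi**2) * np.trapezoid(sin_qr * weighted[None, :], q, axis=1)

    interior = slice(1, None)  # exclude r = 0 where p is identically 0
    i_peak = int(np.argmax(p[interior])) + 1
    peak = _refine_peak(r_grid, p, i_peak)
    dd = DistanceDistribution(r=r_grid, p=p, peak_position=peak)
    dd.ripple_extent = ripple_extent(dd)
    return dd


def intensity_from_distance_distribution(dd: DistanceDistribution, q) -> np.ndarray:
    """Inverse transform I(q) = 4 pi ∫ p(r) sin(qr)/(qr) dr (round-trip check)."""
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    qr = np.outer(q_arr, dd.r)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr == 0.0, 1.0, np.sin(qr) / qr)
    out = 4.0 * np.pi * np.trapezoid(sinc * dd.p[None, :], dd.r, axis=1)
    return out if np.ndim(q) else out[0]


def ripple_extent(dd: DistanceDistribution, min_amplitude: float = 2e-3) -> float:
    """Extent (Å) of the sign-alternating oscillation at short distances.

    Scans p(r) below the global maximum for sign changes whose amplitude
    exceeds ``min_amplitude`` times max |p|; with at least two crossings the
    extent is the largest crossing distance, otherwise 0.  The oscillation is
    the real-space signature of the wall's internal contrast alternation, so
    a solid body (p >= 0 everywhere) reports 0.
    """
    p, r = dd.p, dd.r
    i_peak = int(np.argmax(p))
    thresh = min_amplitude * float(np.max(np.abs(p)))
    crossings: list[float] = []
    sign = 0
    last_idx = 0
    for i in range(1, i_peak + 1):
        if abs(p[i]) < thresh:
            continue
        s = 1 if p[i] > 0 else -1
        if sign != 0 and s != sign:
            # the oscillation ends where the previous lobe was last visible
            crossings.append(float(r[last_idx]))
        sign = s
        last_idx = i
    if len(crossings) >= 2:
        return crossings[-1]
    return 0.0


def guinier_fit(
    curve: ScatteringCurve,
    qrg_max: float = 0.5,
    min_points: int = 5,
    max_iter: int = 50,
) -> GuinierResult:
    """Iterated Guinier fit: ln I = ln I0 - Rg^2 q^2 / 3 on a low-q window.

    Starting from the lowest ``min_points`` * 3 points, the window is
    re-selected to q * Rg <= qrg_max until the selection is stable.  The
    regression is weighted by (I / sigma)^2 when uncertainties are present.
    """
    q, intensity = curve.q, curve.intensity
    usable = intensity > 0
    if usable.sum() < min_points:
        raise NoGuinierRegimeError("too few positive intensities")
    q2 = q**2
    ln_i = np.where(usable, np.log(np.where(usable, intensity, 1.0)), np.nan)
    if curve.sigma is not None and np.all(curve.sigma[usable] > 0):
        weights = (intensity / curve.sigma) ** 2
    else:
        weights = np.ones_like(q)

    mask = usable & (np.arange(len(q)) < max(min_points * 3, min_points))
    rg = None
    for _ in range(max_iter):
        if mask.sum() < min_points:
            raise NoGuinierRegimeError("fewer than min_points points satisfy the q*Rg bound")
        slope, intercept, cov = _weighted_linfit(q2[mask], ln_i[mask], weights[mask])
        if slope >= 0:
            raise NoGuinierRegimeError("nonnegative ln I vs q^2 slope; no Guinier regime")
        rg = float(np.sqrt(-3.0 * slope))
        new_mask = usable & (q * rg <= qrg_max)
        if new_mask.sum() < min_points:
            new_mask = usable.copy()
            new_mask[np.cumsum(usable) > min_points] = False
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    assert rg is not None
    slope_err = float(np.sqrt(max(cov, 0.0)))
    rg_stderr = 1.5 * slope_err / rg if rg > 0 else np.inf
    q_sel = q[mask]
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(intercept)),
        fit_q_range=(float(q_sel[0]), float(q_sel[-1])),
        rg_stderr=rg_stderr,
        n_points=int(mask.sum()),
    )


def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = a x + b; returns (a, b, var(a))."""
    sw = np.sum(w)
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    a = sxy / sxx
    b = ym - a * xm
    resid = y - (a * x + b)
    dof = max(len(x) - 2, 1)
    var_a = np.sum(w * resid**2) / dof / sxx
    return a, b, var_a
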