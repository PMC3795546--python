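"""Forward scattering model for polydisperse multi-shell vesicles.

The particle is a set of concentric regions (shells).  Region ``i`` is the
material between boundary ``i-1`` and boundary ``i`` and carries a uniform
excess scattering density ("contrast") relative to the solvent.  Region 1 is
the innermost one — for a vesicle, the water pool.  Contrasts are expressed
in relative units of 1e10 cm^-2, so that water is 0 and a protein-filled
core sits near 2.3–2.6.

The orientationally averaged intensity of an ellipsoidal shell particle is

    I_s(q) = integral_0^1 |A(q; r_1(x) ... r_n(x))|^2 dx ,
    r_i(x) = r_i sqrt(1 + x^2 (nu_i^2 - 1)),

with the concentric-sphere amplitude

    A(q) = sum_i drho_i [ V(r_i) Phi(q r_i) - V(r_{i-1}) Phi(q r_{i-1}) ],
    Phi(y) = 3 j_1(y) / y ,  V(r) = (4/3) pi r^3 ,  r_0 = 0,

where j_1 is the first-order spherical Bessel function.  For spherical
shells (all nu_i = 1) the orientation integral collapses and I_s = A^2.

Size polydispersity is a Gaussian number distribution D(R) of the overall
(outermost) radius, truncated below at R_min and renormalized; the measured
intensity is I(q) = integral_{R_min} D(R) I_s(q, R) dR.  When the overall radius
varies, the wall (every region except the water pool) keeps its fitted
thicknesses and only the water pool grows or shrinks, because the lower
size cutoff is set by the bilayer thickness.  A proportional-scaling mode is
available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import spherical_jn
from scipy.stats import truncnorm

from .errors import InvalidConfigurationError, InvalidProfileError, UndefinedRgError

__all__ = [
    "Shell",
    "ShellProfile",
    "SizeDistribution",
    "ScatteringCurve",
    "sphere_form_factor_amplitude",
    "shell_amplitude",
    "intensity_monodisperse",
    "gaussian_number_distribution",
    "sample_radii",
    "intensity_polydisperse",
    "analytic_rg",
]


def sphere_form_factor_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized sphere amplitude Phi(x) = 3 j1(x)/x with Phi(0) = 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    # series 1 - x^2/10 + O(x^4) avoids 0/0 at the origin
    return np.where(small, 1.0 - x * x / 10.0, 3.0 * spherical_jn(1, safe) / safe)


@dataclass(frozen=True)
class Shell:
    """One concentric region of the particle.

    Parameters
    ----------
    outer_semi_axis:
        Equatorial semi-axis of the region's outer boundary, in Å.
    contrast:
        Average excess scattering density of the region, in relative units
        (1 unit = 1e10 cm^-2).
    axial_ratio:
        Ratio of the polar to the equatorial semi-axis; 1 for a sphere.
    """

    outer_semi_axis: float
    contrast: float
    axial_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (self.outer_semi_axis > 0 and np.isfinite(self.outer_semi_axis)):
            raise InvalidProfileError(f"outer_semi_axis must be > 0, got {self.outer_semi_axis}")
        if not (self.axial_ratio > 0 and np.isfinite(self.axial_ratio)):
            raise InvalidProfileError(f"axial_ratio must be > 0, got {self.axial_ratio}")
        if not np.isfinite(self.contrast):
            raise InvalidProfileError(f"contrast must be finite, got {self.contrast}")


@dataclass(frozen=True)
class ShellProfile:
    """Ordered concentric regions; region 1 (innermost) is the water pool."""

    shells: tuple[Shell, ...]

    def __post_init__(self) -> None:
        shells = tuple(self.shells)
        object.__setattr__(self, "shells", shells)
        if len(shells) < 1:
            raise InvalidProfileError("profile needs at least one shell")
        radii = [s.outer_semi_axis for s in shells]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise InvalidProfileError(f"shell radii must be strictly increasing, got {radii}")

    @property
    def n(self) -> int:
        return len(self.shells)

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.outer_semi_axis for s in self.shells])

    @property
    def contrasts(self) -> np.ndarray:
        return np.array([s.contrast for s in self.shells])

    @property
    def axial_ratios(self) -> np.ndarray:
        return np.array([s.axial_ratio for s in self.shells])

    @property
    def is_spherical(self) -> bool:
        return bool(np.all(self.axial_ratios == 1.0))

    @property
    def wall_thickness(self) -> float:
        """Total thickness of everything outside the water pool, in Å."""
        r = self.radii
        return float(r[-1] - r[0]) if self.n > 1 else 0.0

    @property
    def thicknesses(self) -> np.ndarray:
        """Radial thickness of each region (region 1 = pool radius)."""
        return np.diff(np.concatenate([[0.0], self.radii]))

    def with_core_contrast(self, contrast: float) -> "ShellProfile":
        """Return a copy with the water-pool (innermost) contrast replaced."""
        first = replace(self.shells[0], contrast=float(contrast))
        return ShellProfile((first,) + self.shells[1:])

    def with_contrasts(self, contrasts: Sequence[float]) -> "ShellProfile":
        if len(contrasts) != self.n:
            raise InvalidProfileError("contrast count mismatch")
        return ShellProfile(tuple(replace(s, contrast=float(c)) for s, c in zip(self.shells, contrasts)))

    def boundaries_at_radius(self, outer_radius, mode: str = "pool") -> np.ndarray:
        """Boundary radii when the overall radius is ``outer_radius``.

        mode "pool" keeps wall thicknesses fixed and varies the water pool;
        mode "proportional" scales every boundary by outer_radius / r_n.
        Returns an array of shape ``outer_radius.shape + (n,)``.
        """
        R = np.atleast_1d(np.asarray(outer_radius, dtype=float))
        r = self.radii
        if mode == "pool":
            offsets = r[-1] - r  # distance of each boundary below the surface
            out = R[..., None] - offsets[None, :]
            if np.any(out <= 0):
                raise InvalidConfigurationError(
                    "overall radius smaller than the wall thickness; increase R_min"
                )
        elif mode == "proportional":
            out = R[..., None] * (r / r[-1])[None, :]
        else:
            raise ValueError(f"unknown polydispersity mode {mode!r}")
        return out


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated Gaussian number distribution of the overall particle radius.

    ``mean_radius`` and ``sigma`` are the mean and standard deviation of the
    parent Gaussian (Å); ``r_min`` is the lower truncation set by the wall
    thickness.  The density is renormalized to unit integral on
    [r_min, infinity).  ``sigma = 0`` degenerates to a point mass.
    """

    mean_radius: float
    sigma: float
    r_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_radius > 0:
            raise InvalidConfigurationError("mean_radius must be > 0")
        if self.sigma < 0:
            raise InvalidConfigurationError("sigma must be >= 0")
        if self.r_min < 0:
            raise InvalidConfigurationError("r_min must be >= 0")

    def _frozen(self):
        a = (self.r_min - self.mean_radius) / self.sigma
        return truncnorm(a, np.inf, loc=self.mean_radius, scale=self.sigma)


def gaussian_number_distribution(dist: SizeDistribution, R) -> np.ndarray:
    """Density D(R) of the truncated Gaussian size distribution, in Å^-1.

    Integrates to 1 over [r_min, inf).  For ``sigma = 0`` the distribution is
    a point mass at the mean; the density is represented as inf at exactly
    the mean radius and 0 elsewhere.
    """
    R = np.asarray(R, dtype=float)
    if dist.sigma == 0.0:
        return np.where(R == dist.mean_radius, np.inf, 0.0)
    return dist._frozen().pdf(R)


def sample_radii(dist: SizeDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw radii by inverse-CDF sampling of the truncated Gaussian."""
    if dist.sigma == 0.0:
        return np.full(n, dist.mean_radius)
    return dist._frozen().ppf(rng.uniform(size=n))


def _amplitude(
    q: np.ndarray,
    radii: np.ndarray,
    contrasts: np.ndarray,
    volumes: np.ndarray | None = None,
) -> np.ndarray:
    """Concentric-shell amplitude for a batch of boundary sets.

    q : (m,), radii : (k, n) ascending along the last axis, contrasts : (n,).
    ``radii`` set the oscillation scale (the argument of Phi); ``volumes``
    are the enclosed volumes of the boundaries, defaulting to the sphere
    volumes of ``radii``.  For an ellipsoid of revolution the volume is
    orientation-independent while the effective Phi radius is not, which is
    why the two are allowed to differ.  Returns (m, k) in relative units * Å^3.
    """
    x = q[:, None, None] * radii[None, :, :]
    if volumes is None:
        volumes = (4.0 / 3.0) * np.pi * radii**3
    else:
        volumes = np.broadcast_to(volumes, radii.shape)
    vol_phi = volumes[None, :, :] * sphere_form_factor_amplitude(x)
    # annular-region bookkeeping: each region's own contrast times the
    # difference of consecutive enclosed-body amplitudes (r_0 = 0 term is 0)
    inner = np.concatenate([np.zeros_like(vol_phi[:, :, :1]), vol_phi[:, :, :-1]], axis=2)
    return np.einsum("mkn,n->mk", vol_phi - inner, contrasts)


def shell_amplitude(profile: ShellProfile, q) -> np.ndarray:
    """Scattering amplitude A(q) of a spherical multi-shell particle.

    A(q) = sum_i drho_i [V(r_i) Phi(q r_i) - V(r_{i-1}) Phi(q r_{i-1})],
    so A(0) is the net excess scattering mass sum_i drho_i (V_i - V_{i-1}).
    """
    if not profile.is_spherical:
        raise InvalidProfileError("shell_amplitude requires a spherical profile (all axial ratios 1)")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q_arr < 0):
        raise ValueError("q must be >= 0")
    out = _amplitude(q_arr, profile.radii[None, :], profile.contrasts)[:, 0]
    return out if np.ndim(q) else out[0]


def _gauss_legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def intensity_monodisperse(profile: ShellProfile, q, n_orient: int = 64) -> np.ndarray:
    """Orientationally averaged intensity I_s(q) of one particle.

    Spherical profiles use |A(q)|^2 directly; ellipsoidal ones average the
    squared amplitude over orientation with fixed-order Gauss–Legendre
    quadrature on x in [0, 1], where each semi-axis maps to
    r_i sqrt(1 + x^2 (nu_i^2 - 1)).
    """
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if profile.is_spherical:
        out = _amplitude(q_arr, profile.radii[None, :], profile.contrasts)[:, 0] ** 2
    else:
        x, w = _gauss_legendre_01(n_orient)
        nu = profile.axial_ratios
        radii_x = profile.radii[None, :] * np.sqrt(1.0 + x[:, None] ** 2 * (nu**2 - 1.0)[None, :])
        volumes = (4.0 / 3.0) * np.pi * nu * profile.radii**3  # true ellipsoid volumes
        amp = _amplitude(q_arr, radii_x, profile.contrasts, volumes=volumes)
        out = amp**2 @ w
    return out if np.ndim(q) else out[0]


def intensity_polydisperse(
    profile: ShellProfile,
    dist: SizeDistribution,
    q,
    n_radius: int = 201,
    n_orient: int = 64,
    mode: str = "pool",
    n_sigma: float = 6.0,
) -> np.ndarray:
    """Size-distribution-averaged intensity I(q) = ∫ D(R) I_s(q, R) dR.

    The integral runs over [r_min, mean + n_sigma * sigma] with ``n_radius``
    Gauss–Legendre nodes.  At each overall radius R the boundaries follow
    ``ShellProfile.boundaries_at_radius`` (default: fixed wall thicknesses,
    variable water pool).
    """
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if mode == "pool" and dist.r_min < profile.wall_thickness:
        raise InvalidConfigurationError(
            f"r_min = {dist.r_min} Å is smaller than the wall thickness "
            f"{profile.wall_thickness} Å; the water pool would have negative radius"
        )
    if dist.sigma == 0.0:
        radii = profile.boundaries_at_radius(dist.mean_radius, mode=mode)[0]
        prof = _profile_with_radii(profile, radii)
        out = intensity_monodisperse(prof, q_arr, n_orient=n_orient)
        return out if np.ndim(q) else out[0]

    lo = max(dist.r_min, profile.wall_thickness if mode == "pool" else 0.0)
    hi = dist.mean_radius + n_sigma * dist.sigma
    if hi <= lo:
        raise InvalidConfigurationError("size distribution support is empty")
    x, w = np.polynomial.legendre.leggauss(n_radius)
    R = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    wR = 0.5 * (hi - lo) * w * gaussian_number_distribution(dist, R)

    radii = profile.boundaries_at_radius(R, mode=mode)  # (k, n)
    if profile.is_spherical:
        amp = _amplitude(q_arr, radii, profile.contrasts)
        out = (amp**2) @ wR
    else:
        xo, wo = _gauss_legendre_01(n_orient)
        nu = profile.axial_ratios
        volumes = (4.0 / 3.0) * np.pi * nu[None, :] * radii**3
        out = np.zeros_like(q_arr)
        for xi, wi in zip(xo, wo):
            radii_x = radii * np.sqrt(1.0 + xi**2 * (nu**2 - 1.0))[None, :]
            out += wi * ((_amplitude(q_arr, radii_x, profile.contrasts, volumes=volumes) ** 2) @ wR)
    return out if np.ndim(q) else out[0]


def _profile_with_radii(profile: ShellProfile, radii: np.ndarray) -> ShellProfile:
    return ShellProfile(
        tuple(replace(s, outer_semi_axis=float(r)) for s, r in zip(profile.shells, radii))
    )


def analytic_rg(profile: ShellProfile, at_radius: float | None = None) -> float:
    """Closed-form radius of gyration of a spherical multi-shell particle.

    Rg^2 = (3/5) * sum_i drho_i (r_i^5 - r_{i-1}^5) / sum_i drho_i (r_i^3 - r_{i-1}^3)

    ``at_radius`` optionally re-evaluates the profile with its overall radius
    moved to the given value at fixed wall thicknesses (variable pool).
    """
    if not profile.is_spherical:
        raise InvalidProfileError("analytic_rg requires a spherical profile")
    radii = profile.radii if at_radius is None else profile.boundaries_at_radius(at_radius)[0]
    r_lo = np.concatenate([[0.0], radii[:-1]])
    rho = profile.contrasts
    num = np.sum(rho * (radii**5 - r_lo**5))
    den = np.sum(rho * (radii**3 - r_lo**3))
    if den == 0 or not np.isfinite(den):
        raise UndefinedRgError("zero net excess scattering mass")
    rg2 = 0.6 * num / den
    if rg2 <= 0:
        raise UndefinedRgError(f"negative Rg^2 = {rg2}")
    return float(np.sqrt(rg2))


@dataclass
class ScatteringCurve:
    """A 1-D scattering curve: q grid (Å^-1), intensities, optional sigmas."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")

    def __len__(self) -> int:
        return len(self.q)
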