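"""Independent brute-force oracles used to validate the fast implementations.

Everything here deliberately avoids the package's computational paths:
amplitudes use the boundary-difference bookkeeping with an explicit
sin/cos sphere form factor, integrals are dense Riemann/Simpson sums, and
real-space distributions come from direct autocorrelation of the radial
density.
"""

import numpy as np
from scipy.integrate import simpson


def sphere_phi(x):
    """3 (sin x - x cos x) / x^3, explicit form, series near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x * x / 10.0, 3.0 * (np.sin(safe) - safe * np.cos(safe)) / safe**3)


def boundary_amplitude(radii, contrasts, q):
    """A(q) via the boundary-difference convention.

    Each boundary r_i carries the contrast step (rho_i - rho_{i+1}) of a
    solid sphere of that radius (rho_{n+1} = 0); algebraically identical to
    the annular-region sum.
    """
    radii = np.asarray(radii, dtype=float)
    contrasts = np.asarray(contrasts, dtype=float)
    steps = contrasts - np.concatenate([contrasts[1:], [0.0]])
    q = np.atleast_1d(np.asarray(q, dtype=float))
    vol = (4.0 / 3.0) * np.pi * radii**3
    return np.sum(steps * vol * sphere_phi(np.outer(q, radii)), axis=1)


def radial_quadrature_amplitude(radii, contrasts, q, n_total=10_000):
    """A(q) = 4 pi \\int rho(r) r^2 sin(qr)/(qr) dr, piecewise Simpson.

    The grid is split at the shell boundaries so each Simpson panel sees a
    smooth integrand; ~n_total points overall.
    """
    radii = np.asarray(radii, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    edges = np.concatenate([[0.0], radii])
    out = np.zeros(len(q))
    n_per = max(int(n_total / len(radii)) | 1, 101)
    for lo, hi, rho in zip(edges[:-1], edges[1:], contrasts):
        r = np.linspace(lo, hi, n_per)
        qr = np.outer(q, r)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qr == 0.0, 1.0, np.sin(qr) / qr)
        out += 4.0 * np.pi * rho * simpson(r[None, :] ** 2 * sinc, x=r, axis=1)
    return out


def orientation_average_trapezoid(radii, contrasts, axial_ratios, q, n=100_000):
    """Dense-trapezoid orientation average of |A|^2 for an ellipsoidal shell.

    Ellipsoid-of-revolution convention: each boundary keeps its true volume
    (4/3) pi nu r^3 while the Phi argument uses the orientation-dependent
    effective radius r sqrt(1 + x^2 (nu^2 - 1)).
    """
    x = np.linspace(0.0, 1.0, n)
    nu = np.asarray(axial_ratios, dtype=float)
    radii = np.asarray(radii, dtype=float)
    contrasts = np.asarray(contrasts, dtype=float)
    steps = contrasts - np.concatenate([contrasts[1:], [0.0]])
    vol = (4.0 / 3.0) * np.pi * nu * radii**3
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.empty(len(q))
    for j, qj in enumerate(q):
        r_x = radii[None, :] * np.sqrt(1.0 + x[:, None] ** 2 * (nu**2 - 1.0)[None, :])
        amp = np.sum(steps * vol * sphere_phi(qj * r_x), axis=1)
        out[j] = np.trapezoid(amp**2, x)
    return out


def polydisperse_riemann(radii, contrasts, dist, q, n_r=2000, n_sigma=6.0):
    """Riemann-sum size average of |A|^2 with fixed wall thicknesses."""
    wall = radii[-1] - radii[0]
    lo = max(dist.r_min, wall)
    hi = dist.mean_radius + n_sigma * dist.sigma
    R = np.linspace(lo, hi, n_r)
    from scipy.stats import truncnorm

    a = (dist.r_min - dist.mean_radius) / dist.sigma
    density = truncnorm.pdf(R, a, np.inf, loc=dist.mean_radius, scale=dist.sigma)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    offsets = radii[-1] - np.asarray(radii)
    out = np.zeros(len(q))
    for Rk, Dk in zip(R, density):
        amp = boundary_amplitude(Rk - offsets, contrasts, q)
        out += Dk * amp**2
    return out * (R[1] - R[0])


def autocorrelation_pr(radii, contrasts, r_grid, n_s=4000):
    """p(r) by direct autocorrelation of the spherically symmetric density.

    p(r) = 8 pi^2 r \\int s rho(s) [ \\int_{|s-r|}^{s+r} u rho(u) du ] ds,
    evaluated with a cumulative-trapezoid inner integral.
    """
    r_max = radii[-1]
    s = np.linspace(0.0, r_max, n_s)
    rho = np.zeros_like(s)
    edges = np.concatenate([[0.0], radii])
    for lo, hi, c in zip(edges[:-1], edges[1:], contrasts):
        rho[(s > lo) & (s <= hi)] = c
    u_rho = s * rho
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (u_rho[1:] + u_rho[:-1]) * np.diff(s))])

    def integral_u(a, b):
        # \int_a^b u rho(u) du via the cumulative table (clipped to support)
        a = np.clip(a, s[0], s[-1])
        b = np.clip(b, s[0], s[-1])
        return np.interp(b, s, cum) - np.interp(a, s, cum)

    out = np.empty(len(r_grid))
    for i, r in enumerate(r_grid):
        inner = integral_u(np.abs(s - r), s + r)
        out[i] = 8.0 * np.pi**2 * r * np.trapezoid(u_rho * inner, s)
    return out


def moment_guinier_rg(radii, contrasts, dist, n_r=4000, n_sigma=6.0):
    """Apparent low-q Rg of the polydisperse shell model from closed forms.

    Guinier's law on a mixture gives Rg_app^2 = sum w I0(R) Rg(R)^2 / sum
    w I0(R) with I0(R) the squared net excess mass and Rg(R) the closed-form
    shell radius of gyration, both evaluated with fixed wall thicknesses.
    """
    from scipy.stats import truncnorm

    wall = radii[-1] - radii[0]
    lo = max(dist.r_min, wall)
    hi = dist.mean_radius + n_sigma * dist.sigma
    R = np.linspace(lo + 1e-9, hi, n_r)
    a = (dist.r_min - dist.mean_radius) / dist.sigma
    density = truncnorm.pdf(R, a, np.inf, loc=dist.mean_radius, scale=dist.sigma)
    offsets = radii[-1] - np.asarray(radii)
    contrasts = np.asarray(contrasts, dtype=float)
    i0 = np.empty(len(R))
    rg2 = np.empty(len(R))
    for k, Rk in enumerate(R):
        rk = Rk - offsets
        r_lo = np.concatenate([[0.0], rk[:-1]])
        mass3 = np.sum(contrasts * (rk**3 - r_lo**3))
        mass5 = np.sum(contrasts * (rk**5 - r_lo**5))
        i0[k] = ((4.0 / 3.0) * np.pi * mass3) ** 2
        rg2[k] = 0.6 * mass5 / mass3
    w = density * i0
    return float(np.sqrt(np.sum(w * rg2) / np.sum(w)))


def random_shell_profile(rng, n_min=1, n_max=6, r_max=500.0):
    """Random spherical shell geometry: ascending radii + O(1) contrasts."""
    n = int(rng.integers(n_min, n_max + 1))
    radii = np.sort(rng.uniform(20.0, r_max, size=n))
    while np.any(np.diff(radii) < 2.0):
        radii = np.sort(rng.uniform(20.0, r_max, size=n))
    contrasts = rng.uniform(-3.0, 3.0, size=n)
    # keep the net mass clearly nonzero so relative comparisons are stable
    if abs(np.sum(contrasts * np.diff(np.concatenate([[0.0], radii**3])))) < 1e3:
        contrasts[-1] += 1.0
    return radii, contrasts
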