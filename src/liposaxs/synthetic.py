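"""Synthetic inputs: the canonical vesicle fixture and noisy curve generators.

No public scattering database carries curves for the ganglioside
G_D1/cholesterol/egg-PC vesicles this pipeline targets, so every input is
generated here.  The canonical fixture is a five-region wall around a water
pool whose sign pattern follows the known asymmetric bilayer of
ganglioside-bearing vesicles (inside out): a dense hydration layer (+), the
inner phosphocholine headgroups (+, high), the hydrocarbon core (-), the
outer headgroups (+, high) and the protruding oligosaccharide chains
(+, low).  Thicknesses and contrast magnitudes are frozen constants,
calibrated once (scripts/calibrate_fixture.py) so that the empty-vesicle
model reproduces the qualitative observables expected of such vesicles: a
p(r) oscillation extending to roughly 55 Å, a low-q shoulder near
q = 0.01 Å^-1 with a broad rounded peak in 0.04-0.2 Å^-1, and a Guinier
radius between 500 and 650 Å at a mean outer radius of 400 Å with 30 %
polydispersity.

The noise generator emulates counting statistics: a relative floor plus a
Poisson-like sqrt(I) term, both Gaussian-applied, with the stream fixed by
an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shell_model import (
    ScatteringCurve,
    Shell,
    ShellProfile,
    SizeDistribution,
    intensity_polydisperse,
    sphere_form_factor_amplitude,
)

__all__ = [
    "NoiseModel",
    "CanonicalFixture",
    "canonical_fixture",
    "synth_curve",
    "synth_mixture",
    "default_q_grid",
]

# Frozen canonical-fixture constants (inside out).  Thicknesses in Å,
# contrasts in relative units of 1e10 cm^-2.  See scripts/calibrate_fixture.py.
CANONICAL_LAYERS: tuple[tuple[str, float, float], ...] = (
    ("hydration", 6.0, 0.6),
    ("inner_headgroup", 9.0, 2.5),
    ("hydrocarbon_core", 24.0, -2.0),
    ("outer_headgroup", 9.0, 2.5),
    ("oligosaccharide", 12.0, 0.5),
)
CANONICAL_MEAN_RADIUS = 400.0  # Å, mean outermost radius
CANONICAL_SIGMA_FRACTION = 0.30  # 30 % polydispersity


@dataclass(frozen=True)
class CanonicalFixture:
    """The canonical empty-vesicle model: wall profile plus size distribution."""

    profile: ShellProfile
    distribution: SizeDistribution
    layer_names: tuple[str, ...]

    def filled(self, core_contrast: float) -> "CanonicalFixture":
        """Same fixture with the water-pool contrast set (protein occlusion)."""
        return CanonicalFixture(
            profile=self.profile.with_core_contrast(core_contrast),
            distribution=self.distribution,
            layer_names=self.layer_names,
        )


def canonical_fixture(core_contrast: float = 0.0) -> CanonicalFixture:
    """Build the canonical five-layer vesicle fixture.

    ``core_contrast`` is the water-pool contrast in relative units: 0 for the
    empty vesicle, up to ~2.6 for a pool fully occupied by protein.
    """
    wall = sum(t for _, t, _ in CANONICAL_LAYERS)
    pool_radius = CANONICAL_MEAN_RADIUS - wall
    shells = [Shell(outer_semi_axis=pool_radius, contrast=core_contrast)]
    names = ["water_pool"]
    r = pool_radius
    for name, thickness, contrast in CANONICAL_LAYERS:
        r += thickness
        shells.append(Shell(outer_semi_axis=r, contrast=contrast))
        names.append(name)
    dist = SizeDistribution(
        mean_radius=CANONICAL_MEAN_RADIUS,
        sigma=CANONICAL_SIGMA_FRACTION * CANONICAL_MEAN_RADIUS,
        r_min=wall,
    )
    return CanonicalFixture(
        profile=ShellProfile(tuple(shells)), distribution=dist, layer_names=tuple(names)
    )


@dataclass(frozen=True)
class NoiseModel:
    """Heteroscedastic counting-statistics noise.

    sigma_I(q) = floor * I(q) + scale * sqrt(I(q)); the perturbation is
    Gaussian with that standard deviation and the stream is fixed by
    ``seed``.  ``background`` is a flat residual level (intensity units)
    added to the model before the noise: measured solution curves plateau at
    high q where incompletely subtracted buffer/incoherent scattering takes
    over, and several qualitative comparisons (e.g. where free protein
    changes a curve the most) only make sense against that plateau.
    """

    floor: float = 0.01
    scale: float = 0.0
    seed: int = 0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.floor < 0 or self.scale < 0 or self.background < 0:
            raise ValueError("noise components must be >= 0")

    def sigma(self, intensity: np.ndarray) -> np.ndarray:
        return self.floor * intensity + self.scale * np.sqrt(np.maximum(intensity, 0.0))


def default_q_grid(q_min: float = 3e-3, q_max: float = 0.3, n: int = 1200) -> np.ndarray:
    """Uniform q grid covering the small-angle regime of the experiment."""
    return np.linspace(q_min, q_max, n)


def synth_curve(
    profile: ShellProfile,
    dist: SizeDistribution,
    noise: NoiseModel | None = None,
    q_grid: np.ndarray | None = None,
    n_radius: int = 201,
) -> ScatteringCurve:
    """Noisy synthetic curve from the polydisperse shell model.

    With a zero noise model (or ``noise=None`` and default floor 0) the exact
    model curve is returned; otherwise Gaussian heteroscedastic noise is
    added and the sigma column populated.  Reproducible per seed.
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    model = intensity_polydisperse(profile, dist, q, n_radius=n_radius)
    if noise is None:
        return ScatteringCurve(q=q, intensity=model)
    model = model + noise.background
    sigma = noise.sigma(model)
    if noise.floor == 0 and noise.scale == 0:
        return ScatteringCurve(q=q, intensity=model, sigma=sigma)
    rng = np.random.default_rng(noise.seed)
    return ScatteringCurve(q=q, intensity=model + rng.normal(0.0, 1.0, size=q.size) * sigma, sigma=sigma)


def synth_mixture(
    luv_curve: ScatteringCurve,
    protein_rg: float = 16.0,
    protein_i0_fraction: float = 0.0,
    noise: NoiseModel | None = None,
) -> ScatteringCurve:
    """Add an incoherent free-protein term to a vesicle curve.

    Emulates the before-spin-filtration scenario: un-entrapped globular
    protein (monomer scale, Rg ~ 16 Å) contributes an independent
    sphere-form-factor term whose forward intensity is
    ``protein_i0_fraction`` times the vesicle curve's lowest-q intensity.
    """
    if protein_rg <= 0:
        raise ValueError("protein_rg must be > 0")
    if protein_i0_fraction == 0.0:
        return luv_curve
    r_sphere = np.sqrt(5.0 / 3.0) * protein_rg
    protein = (
        protein_i0_fraction
        * float(luv_curve.intensity[0])
        * sphere_form_factor_amplitude(luv_curve.q * r_sphere) ** 2
    )
    total = luv_curve.intensity + protein
    sigma = luv_curve.sigma
    if noise is not None and (noise.floor > 0 or noise.scale > 0):
        sigma = noise.sigma(total)
        rng = np.random.default_rng(noise.seed)
        total = total + rng.normal(0.0, 1.0, size=total.size) * sigma
    return ScatteringCurve(q=luv_curve.q, intensity=total, sigma=sigma)
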