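"""Forward-model unit and property tests against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from liposaxs import (
    Shell,
    ShellProfile,
    SizeDistribution,
    analytic_rg,
    gaussian_number_distribution,
    intensity_monodisperse,
    intensity_polydisperse,
    shell_amplitude,
)
from liposaxs.errors import InvalidConfigurationError, InvalidProfileError, UndefinedRgError
from liposaxs.shell_model import sample_radii

from conftest import uniform_sphere
from oracles import (
    boundary_amplitude,
    orientation_average_trapezoid,
    polydisperse_riemann,
    radial_quadrature_amplitude,
    random_shell_profile,
)


def make_profile(radii, contrasts, nu=None):
    nu = nu if nu is not None else [1.0] * len(radii)
    return ShellProfile(tuple(Shell(r, c, a) for r, c, a in zip(radii, contrasts, nu)))


class TestShellAmplitude:
    def test_forward_amplitude_is_excess_volume(self):
        sphere = uniform_sphere(400.0, 1.0)
        expected = 4.0 / 3.0 * np.pi * 400.0**3
        assert shell_amplitude(sphere, 0.0) == pytest.approx(expected, rel=1e-12)
        # continuous at q -> 0
        assert shell_amplitude(sphere, 1e-9) == pytest.approx(expected, rel=1e-8)

    def test_first_zero_of_uniform_sphere(self):
        # 3 j1(x)/x first vanishes at x = 4.493409...
        sphere = uniform_sphere(400.0, 1.0)
        f = lambda q: shell_amplitude(sphere, q)
        q_zero = brentq(f, 3.5 / 400.0, 5.5 / 400.0, xtol=1e-14)
        assert q_zero * 400.0 == pytest.approx(4.493409, abs=1e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_amplitude_matches_radial_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        radii, contrasts = random_shell_profile(rng)
        profile = make_profile(radii, contrasts)
        q = np.linspace(0.0, 0.25, 40)
        ours = shell_amplitude(profile, q)
        oracle = radial_quadrature_amplitude(radii, contrasts, q)
        assert np.all(np.abs(ours - oracle) <= 1e-6 * np.max(np.abs(oracle)))

    def test_annular_equals_boundary_difference_convention(self):
        rng = np.random.default_rng(7)
        radii, contrasts = random_shell_profile(rng, n_min=3, n_max=6)
        profile = make_profile(radii, contrasts)
        q = np.linspace(0.0, 0.3, 64)
        np.testing.assert_allclose(
            shell_amplitude(profile, q), boundary_amplitude(radii, contrasts, q), rtol=1e-12
        )

    def test_non_monotone_radii_rejected(self):
        with pytest.raises(InvalidProfileError):
            make_profile([100.0, 90.0], [1.0, 1.0])

    def test_ellipsoid_requires_spherical(self):
        prof = make_profile([100.0], [1.0], nu=[1.5])
        with pytest.raises(InvalidProfileError):
            shell_amplitude(prof, 0.01)


class TestIntensityMonodisperse:
    def test_spherical_case_is_amplitude_squared(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            radii, contrasts = random_shell_profile(rng)
            profile = make_profile(radii, contrasts)
            q = np.linspace(0.0, 0.3, 50)
            np.testing.assert_allclose(
                intensity_monodisperse(profile, q),
                shell_amplitude(profile, q) ** 2,
                rtol=1e-10,
                atol=1e-10 * np.max(shell_amplitude(profile, q) ** 2),
            )

    def test_ellipsoid_against_dense_trapezoid(self):
        profile = make_profile([400.0], [1.0], nu=[1.5])
        q = np.array([0.002, 0.008, 0.02, 0.05])
        ours = intensity_monodisperse(profile, q)
        oracle = orientation_average_trapezoid([400.0], [1.0], [1.5], q)
        assert np.all(np.abs(ours - oracle) <= 1e-6 * np.abs(oracle))

    def test_forward_intensity_is_orientation_free_mass_square(self):
        # I(0) = (sum_i drho_i (V_i - V_{i-1}))^2 with true ellipsoid volumes,
        # exactly reproduced by the orientation quadrature
        radii = np.array([300.0, 340.0, 400.0])
        contrasts = np.array([0.5, 2.0, -1.0])
        for nu in (1.0, 1.4, 0.7):
            vol = 4.0 / 3.0 * np.pi * nu * radii**3
            annular = vol - np.concatenate([[0.0], vol[:-1]])
            expected = float(np.sum(contrasts * annular)) ** 2
            prof = make_profile(radii, contrasts, nu=[nu] * 3)
            assert intensity_monodisperse(prof, 0.0) == pytest.approx(expected, rel=1e-9)


class TestSizeDistribution:
    def test_truncated_gaussian_normalizes(self):
        dist = SizeDistribution(mean_radius=400.0, sigma=120.0, r_min=60.0)
        R = np.linspace(60.0, 400.0 + 8 * 120.0, 200_001)
        integral = np.trapezoid(gaussian_number_distribution(dist, R), R)
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_when_truncation_is_remote(self):
        dist = SizeDistribution(mean_radius=1000.0, sigma=50.0, r_min=0.0)
        delta = np.array([10.0, 37.0, 120.0])
        np.testing.assert_allclose(
            gaussian_number_distribution(dist, 1000.0 - delta),
            gaussian_number_distribution(dist, 1000.0 + delta),
            rtol=1e-12,
        )

    def test_inverse_cdf_sampling_mean(self):
        # truncation at 60 A barely perturbs the mean at sigma = 30 %
        dist = SizeDistribution(mean_radius=400.0, sigma=120.0, r_min=60.0)
        draws = sample_radii(dist, 100_000, np.random.default_rng(42))
        assert draws.min() >= 60.0
        assert draws.mean() == pytest.approx(400.0, abs=2.0)

    def test_sigma_zero_is_point_mass(self):
        dist = SizeDistribution(mean_radius=400.0, sigma=0.0)
        assert gaussian_number_distribution(dist, 400.0) == np.inf
        assert gaussian_number_distribution(dist, 399.0) == 0.0


class TestIntensityPolydisperse:
    def test_degenerate_distribution_equals_monodisperse(self, fixture_model):
        profile = fixture_model.profile
        dist = SizeDistribution(mean_radius=400.0, sigma=0.0, r_min=60.0)
        q = np.linspace(1e-3, 0.3, 100)
        np.testing.assert_allclose(
            intensity_polydisperse(profile, dist, q),
            intensity_monodisperse(profile, q),
            rtol=1e-12,
        )

    def test_against_dense_riemann_sum(self, fixture_model):
        profile = fixture_model.profile
        dist = fixture_model.distribution
        q = np.linspace(1e-3, 0.25, 60)
        ours = intensity_polydisperse(profile, dist, q)
        oracle = polydisperse_riemann(profile.radii, profile.contrasts, dist, q)
        assert np.all(np.abs(ours / oracle - 1.0) <= 1e-4)

    def test_forward_intensity_is_mass_square_average(self, fixture_model):
        profile = fixture_model.profile
        dist = fixture_model.distribution
        ours = intensity_polydisperse(profile, dist, 0.0)
        oracle = polydisperse_riemann(profile.radii, profile.contrasts, dist, 0.0)[0]
        assert ours == pytest.approx(oracle, rel=1e-4)

    def test_r_min_below_wall_thickness_rejected(self, fixture_model):
        dist = SizeDistribution(mean_radius=400.0, sigma=120.0, r_min=10.0)
        with pytest.raises(InvalidConfigurationError):
            intensity_polydisperse(fixture_model.profile, dist, 0.01)


class TestAnalyticRg:
    def test_solid_sphere(self):
        assert analytic_rg(uniform_sphere(400.0)) == pytest.approx(np.sqrt(0.6) * 400.0, rel=1e-12)

    def test_thin_shell_limit(self):
        prof = make_profile([399.999, 400.0], [0.0, 1.0])
        assert analytic_rg(prof) == pytest.approx(400.0, rel=1e-4)

    def test_zero_net_mass_is_undefined(self):
        prof = make_profile([200.0, 200.0 * 2 ** (1.0 / 3.0)], [1.0, -1.0])
        with pytest.raises(UndefinedRgError):
            analytic_rg(prof)

    def test_at_radius_shifts_wall(self, fixture_model):
        profile = fixture_model.profile
        rg_500 = analytic_rg(profile, at_radius=500.0)
        shifted = profile.boundaries_at_radius(500.0)[0]
        direct = analytic_rg(make_profile(shifted, profile.contrasts))
        assert rg_500 == pytest.approx(direct, rel=1e-12)


@st.composite
def spherical_profiles(draw):
    n = draw(st.integers(min_value=1, max_value=5))
    radii = sorted(
        draw(
            st.lists(
                st.floats(min_value=20.0, max_value=600.0),
                min_size=n,
                max_size=n,
                unique=True,
            )
        )
    )
    if any(b - a < 1.0 for a, b in zip(radii, radii[1:])):
        radii = [20.0 + 30.0 * i for i in range(n)]
    contrasts = draw(
        st.lists(
            st.floats(min_value=-3.0, max_value=3.0, allow_nan=False),
            min_size=n,
            max_size=n,
        )
    )
    return make_profile(radii, contrasts)


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(profile=spherical_profiles(), c=st.floats(min_value=0.1, max_value=10.0))
    def test_contrast_scaling_squares_intensity(self, profile, c):
        q = np.linspace(0.0, 0.2, 20)
        scaled = profile.with_contrasts(c * profile.contrasts)
        np.testing.assert_allclose(
            intensity_monodisperse(scaled, q),
            c**2 * intensity_monodisperse(profile, q),
            rtol=1e-12,
            atol=1e-30,
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(profile=spherical_profiles())
    def test_intensity_nonnegative(self, profile):
        q = np.linspace(0.0, 0.4, 50)
        assert np.all(intensity_monodisperse(profile, q) >= 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_ellipsoid_reduces_to_spherical_at_unit_axial_ratio(self, seed):
        rng = np.random.default_rng(100 + seed)
        radii, contrasts = random_shell_profile(rng)
        spherical = make_profile(radii, contrasts)
        # same geometry but routed through the orientation-average quadrature
        forced = make_profile(radii, contrasts, nu=[1.0 + 1e-15] * len(radii))
        q = np.linspace(0.0, 0.3, 50)
        ref = intensity_monodisperse(spherical, q)
        assert np.all(
            np.abs(intensity_monodisperse(forced, q) - ref) <= 1e-10 * np.max(ref) + 1e-30
        )
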