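import numpy as np
import pytest

from liposaxs import ScatteringCurve, Shell, ShellProfile, canonical_fixture, intensity_polydisperse

ACCEPTANCE_Q = np.linspace(3e-3, 0.3, 1500)
LOW_Q = np.linspace(1.5e-4, 4e-3, 160)
PR_R_GRID = np.linspace(0.0, 2000.0, 2001)


def uniform_sphere(radius=400.0, contrast=1.0) -> ShellProfile:
    return ShellProfile((Shell(outer_semi_axis=radius, contrast=contrast),))


@pytest.fixture(scope="session")
def fixture_model():
    return canonical_fixture()


@pytest.fixture(scope="session")
def empty_model_curve(fixture_model):
    """Noiseless empty-vesicle model curve on the wide analysis grid."""
    intensity = intensity_polydisperse(
        fixture_model.profile, fixture_model.distribution, ACCEPTANCE_Q
    )
    return ScatteringCurve(q=ACCEPTANCE_Q, intensity=intensity)


@pytest.fixture(scope="session")
def filled_model_curve(fixture_model):
    """Same model with the water pool at the saturation contrast 2.6."""
    intensity = intensity_polydisperse(
        fixture_model.profile.with_core_contrast(2.6), fixture_model.distribution, ACCEPTANCE_Q
    )
    return ScatteringCurve(q=ACCEPTANCE_Q, intensity=intensity)
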