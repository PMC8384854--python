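import numpy as np
import pytest

from nautimorph import (
    Curve,
    LandmarkConfiguration,
    ShellParams,
    SpeciesSpec,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def circle_curve(n=720, radius=1.0, center=(0.0, 0.0), phase=0.0):
    t = phase + np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])
    return Curve(points=pts, closed=True, label="circle")


def random_config(rng, k=12, d=2, scale=1.0):
    return LandmarkConfiguration(coords=scale * rng.normal(size=(k, d)), label="rand")


def small_species_specs(cv=0.0, noise_sd=0.0, angle_noise_sd=1.2):
    """Three compact species for fast pipeline-level tests."""
    specs = []
    for code, aspect, c3, mid, hatch in (
        ("SpA", 1.25, -0.04, 22.0, 7),
        ("SpB", 1.40, 0.04, 25.0, 7),
        ("SpC", 1.32, 0.00, 28.0, 8),
    ):
        params = ShellParams(
            section_aspect=aspect,
            section_shape_coeffs=(0.02, c3, 0.01, 0.0),
            n_chambers=26,
            hatching_chamber=hatch,
            angle_mid=mid,
            angle_noise_sd=angle_noise_sd,
        )
        specs.append(
            SpeciesSpec(
                name=code, region="synthetic", code=code,
                mean_params=params, intraspecific_cv=cv, landmark_noise_sd=noise_sd,
            )
        )
    return specs


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_species_specs(cv=0.01, noise_sd=0.03), n_per_species=2, seed=5)
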