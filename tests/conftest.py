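import numpy as np
import pytest

from memborient.synthetic import (
    AngleMixture,
    TrajectoryParams,
    build_membrane_fixture,
    build_protein_fixture,
    generate_trajectory,
    synthesize,
)


@pytest.fixture(scope="session")
def protein_fixture():
    return build_protein_fixture(seed=0)


@pytest.fixture(scope="session")
def membrane_fixture():
    return build_membrane_fixture(seed=1)


@pytest.fixture(scope="session")
def zero_noise_run(protein_fixture, membrane_fixture):
    """Noise-free GDP-like trajectory: sampled angles are exact ground truth."""
    protein, pc = protein_fixture
    membrane, mc, _ = membrane_fixture
    params = TrajectoryParams(
        n_frames=40, seed=3, thermal_sigma=0.0, switch_sigma=0.0,
        theta=AngleMixture([(95.0, 7.5, 1.0)]),
        phi=AngleMixture([(80.0, 10.0, 0.5), (190.0, 10.0, 0.5)]),
    )
    return generate_trajectory(protein, pc, membrane, mc, params)


@pytest.fixture(scope="session")
def gdp_run():
    """Small noisy GDP-preset run shared across analysis tests."""
    return synthesize(state="gdp", n_frames=60, seed=11)
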