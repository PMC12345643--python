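import pytest

import habitatpipe.phantom as ph
from habitatpipe.tofts import AIFModel


@pytest.fixture(scope="session")
def acq() -> ph.AcquisitionConfig:
    return ph.AcquisitionConfig()


@pytest.fixture(scope="session")
def small_truth() -> ph.PhantomTruth:
    """Small 5-habitat phantom shared across read-only tests."""
    return ph.generate_phantom(grid_dims=(32, 32, 6), seed=3)


@pytest.fixture(scope="session")
def default_truth() -> ph.PhantomTruth:
    """Full-size phantom (64x64x10) for registration / MSI tests."""
    return ph.generate_phantom(seed=5)


@pytest.fixture(scope="session")
def calibrated_aif(acq) -> AIFModel:
    return AIFModel(onset_time=acq.contrast_onset)


def uniform_phantom(params: ph.HabitatParams, grid=(12, 12, 4),
                    seed=0) -> ph.PhantomTruth:
    """Single-habitat phantom with chosen generative parameters."""
    return ph.generate_phantom(
        grid_dims=grid, n_habitats=1, necrotic_fraction=0.0, seed=seed,
        habitat_params=(params,), with_muscle=False,
    )
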