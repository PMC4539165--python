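import numpy as np
import pytest
from scipy import ndimage

from lesionmorph import (
    AnalysisConfig,
    CaseConfig,
    CaseInputs,
    MetamorphosisParams,
    PHASE_1,
    ScalarVolume,
    generate_case,
    metamorphose,
    run_phase,
)


def smooth_disk(center, radius, shape=(32, 32), blur=1.5) -> np.ndarray:
    g = np.indices(shape).astype(float)
    d = np.sqrt(sum((g[i] - center[i]) ** 2 for i in range(len(shape))))
    return ndimage.gaussian_filter((d <= radius).astype(float), blur)


def hard_disk(center, radius, shape=(32, 32)) -> np.ndarray:
    g = np.indices(shape).astype(float)
    d = np.sqrt(sum((g[i] - center[i]) ** 2 for i in range(len(shape))))
    return d <= radius


@pytest.fixture(scope="session")
def translated_disk_path():
    """Metamorphosis of a smoothed disk translated by 2 voxels (geometry-heavy)."""
    src = ScalarVolume(smooth_disk((14, 14), 6))
    tgt = ScalarVolume(smooth_disk((16, 14), 6))
    params = MetamorphosisParams(
        sigma=0.02, kernel_width_mm=6.0, n_timesteps=10, max_iters=1200, tol=1e-6
    )
    return src, tgt, metamorphose(src, tgt, params)


@pytest.fixture(scope="session")
def default_case():
    """One default synthetic case (64x64, two components, both MTT maps)."""
    return generate_case(CaseConfig(seed=11))


@pytest.fixture(scope="session")
def default_phase1_result(default_case):
    """Full phase-1 analysis of the default case at default settings."""
    inputs = CaseInputs.from_synthetic(default_case, "fixture-case")
    return run_phase(inputs, PHASE_1, AnalysisConfig())
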