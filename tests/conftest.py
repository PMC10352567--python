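import numpy as np
import pytest

from glycoquant import (
    DEFAULT_PANEL,
    EffectModel,
    SpectrumModel,
    StudyDesign,
    build_library,
    generate_dataset,
)

NOISELESS_SPECTRUM = SpectrumModel(
    mz_jitter_sd=0.0,
    drift_offset=0.0,
    drift_slope_ppm=0.0,
    n_noise_peaks=0,
    bleed=0.0,
)

NOISELESS_EFFECTS = EffectModel(
    biological_cv=0.0,
    technical_cv=0.0,
    outlier_prob=0.0,
)


@pytest.fixture(scope="session")
def library():
    return build_library(DEFAULT_PANEL)


@pytest.fixture(scope="session")
def noise_free_dataset(library):
    """Small noiseless study: 2 mice/group/sex, 2 weeks, triplicate spots."""
    design = StudyDesign(mice_per_group_sex=2, weeks=(15, 19), seed=7)
    return generate_dataset(
        design, NOISELESS_EFFECTS, NOISELESS_SPECTRUM, library=library
    )


@pytest.fixture(scope="session")
def noisy_dataset(library):
    """Small study with default noise levels, single time point."""
    design = StudyDesign(mice_per_group_sex=5, weeks=(15,), seed=11)
    return generate_dataset(
        design, EffectModel(), SpectrumModel(), library=library
    )
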