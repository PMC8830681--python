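import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from circaquant.synth import (
    ExperimentDesign,
    GroundTruthRhythm,
    phase_for_zenith,
    random_scene,
    rhythm_value,
)


@pytest.fixture(scope="session")
def study_design() -> ExperimentDesign:
    """The study's sampling layout: PS16 start, 4-h interval, 24-h span,
    triplicate."""
    return ExperimentDesign(start=16.0, interval=4.0, span=24.0,
                            replicates=3, seed=0)


@pytest.fixture(scope="session")
def phagocytosis_truth() -> GroundTruthRhythm:
    """A sustained 24-h rhythm peaking at PS32, like the observed uptake."""
    return GroundTruthRhythm(amplitude=1.0, ac_coeff=0.0, period=24.0,
                             phase=phase_for_zenith(32.0, 16.0, 24.0),
                             equilibrium=5.0)


@pytest.fixture(scope="session")
def noisy_catalog(study_design, phagocytosis_truth):
    """50 seeded replicate-resolved series at the study design, 10% noise."""
    rng = np.random.default_rng(20240416)
    tt = study_design.timepoints()
    catalog = {}
    for i in range(50):
        rows = [
            {"time_ps": t, "replicate": r,
             "value": rhythm_value(phagocytosis_truth, t, 16.0)
             + rng.normal(0.0, 0.1)}
            for t in tt for r in (1, 2, 3)
        ]
        catalog[f"series_{i}"] = pd.DataFrame(rows)
    return catalog


@pytest.fixture(scope="session")
def one_scene():
    """One deterministic synthetic scene with ground truth."""
    return random_scene(seed=7, n_cells=12)
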