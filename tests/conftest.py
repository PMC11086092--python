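import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import eegcomplexity as ec
from eegcomplexity import pipeline


@pytest.fixture(autouse=True)
def _quiet_unreliable():
    """Scaling-fit caveats are expected on synthetic noise; keep logs clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ec.features.UnreliableResultWarning)
        yield


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two groups of four subjects, 2 channels, 15 s, with an energy
    effect injected at (ch01, alpha) — shared across integration tests."""
    cfg = ec.CohortConfig(
        n_per_group=(4, 4),
        n_channels=2,
        duration=15.0,
        seed=5,
        effect_spec=(ec.EffectSpec(0, "alpha", "energy", 1.5),),
        group_labels=("G", "B"),
    )
    return cfg, *ec.gen_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    """Per-window and aggregated feature tables of the tiny cohort."""
    _, recordings, subjects = tiny_cohort
    window_table, table = pipeline.extract_cohort_features(
        recordings, subjects, minute_s=None
    )
    return window_table, table
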