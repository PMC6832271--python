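"""Shared fixtures: small seeded synthetic cohorts and series builders."""

from pathlib import Path

import numpy as np
import pytest

from sensorbench import ChannelName, ParameterSeries
from sensorbench import generate_cohort, prepare_channels


COHORT_SEED = 123  # fixed master seed for the shared small cohort


def make_series(v, resolution_ms: float = 100.0, parameter: str = "GSR",
                platform: str = "VP", scale: str = "original",
                t0_ms: float = 0.0) -> ParameterSeries:
    v = np.asarray(v, dtype=float)
    t = t0_ms + resolution_ms * np.arange(v.size)
    return ParameterSeries(ChannelName(parameter, platform), t, v, scale)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory) -> Path:
    """Four-participant cohort (participant index 1 degraded)."""
    root = tmp_path_factory.mktemp("cohort") / "raw"
    generate_cohort(root, n=4, master_seed=COHORT_SEED, degraded_index=1)
    return root


@pytest.fixture(scope="session")
def clean_channels(small_cohort):
    """Prepared channels of the first (clean) participant."""
    return prepare_channels(small_cohort / "RP_01")
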