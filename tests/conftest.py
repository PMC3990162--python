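from __future__ import annotations

import numpy as np
import pytest

from cnaprog.core_io import Direction, Group, reciprocal_overlap
from cnaprog.segmentation import SegmentationParams, call_profile
from cnaprog.synthetic_data import Cohort, CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config) -> Cohort:
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def default_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def cohort_calls(default_cohort, default_params):
    """Non-neutral calls per sample for the default cohort."""
    return {
        p.sample_id: [
            c for c in call_profile(p, default_params) if c.direction is not Direction.NEUTRAL
        ]
        for p in default_cohort.profiles
    }


@pytest.fixture(scope="session")
def progressive_sample_ids(default_cohort) -> list[str]:
    return [
        m.sample_id for m in default_cohort.metas if m.group in (Group.PL, Group.OSCC)
    ]


def matches(call_interval, call_direction, truth_interval, truth_direction, min_ro=0.5) -> bool:
    return (
        call_direction.value == truth_direction.value
        and reciprocal_overlap(call_interval, truth_interval) >= min_ro
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
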