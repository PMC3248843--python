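"""Shared fixtures: tiny synthetic worlds and cohorts, all generated at
test time so the repository carries no data files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tracklink.synth import (
    NULL_PROFILE,
    make_map,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_world():
    return make_map([f"c{i:02d}" for i in range(1, 4)], seed=5)


@pytest.fixture(scope="session")
def null_cohort():
    """3 children x 7 days, verbatim diaries, noiseless tracks."""
    return simulate_cohort(
        n_children=3,
        days=7,
        seed=11,
        lower_profile=NULL_PROFILE,
        higher_profile=NULL_PROFILE,
        p_offroad=0.0,
        noise_sd_m=0.0,
        dropout=0.0,
        artifact_rate=0.0,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """3 children x 7 days with the default realistic degradation."""
    return simulate_cohort(n_children=3, days=7, seed=23)


def make_coded_fixes(
    runs: list[tuple[str, int]],
    participant_id: str = "p1",
    start: str = "2011-03-14 08:00:00",
    epoch_s: float = 10.0,
) -> pd.DataFrame:
    """Build a coded fix frame from (location_code, n_fixes) run specs."""
    codes: list[str] = []
    for code, n in runs:
        codes.extend([code] * n)
    n = len(codes)
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": t0 + pd.to_timedelta(np.arange(n) * epoch_s, unit="s"),
            "lat": 0.0,
            "lon": 0.0,
            "speed": 0.0,
            "hdop": 1.0,
            "nsat": 8,
            "location_code": codes,
        }
    )
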