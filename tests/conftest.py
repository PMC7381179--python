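"""Shared fixtures: synthetic cohorts and label panels reused across tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mepmorph import generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def cohort120():
    """A 120-patient synthetic cohort shared by read-only tests."""
    return generate_cohort(120, rng_seed=7)


@pytest.fixture(scope="session")
def mixed_series():
    """Short series with mixed dynamics (sine, noise, AR, sums) for oracle checks."""
    rng = np.random.default_rng(20200728)
    series = []
    for i in range(100):
        n = int(rng.integers(50, 301))
        kind = i % 4
        t = np.arange(n)
        if kind == 0:
            s = np.sin(2 * np.pi * t / rng.uniform(5, 40)) + 0.2 * rng.standard_normal(n)
        elif kind == 1:
            s = rng.standard_normal(n)
        elif kind == 2:  # AR(1)
            s = np.empty(n)
            s[0] = rng.standard_normal()
            phi = rng.uniform(0.5, 0.95)
            for j in range(1, n):
                s[j] = phi * s[j - 1] + rng.standard_normal()
        else:
            s = np.sin(2 * np.pi * t / 15.0) + rng.standard_normal(n)
        series.append(s)
    return series
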