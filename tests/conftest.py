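"""Shared fixtures.

Cohort fixtures use a coarsened geometry (4 µm/px, ~3.6 mm field) so tests
run quickly; the planted effect sizes are the generator defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tphen import RoiConfig, SimulationConfig, clinical_frame, generate_cohort
from tphen.roi_features import extract_feature_table

TEST_GEOMETRY = dict(image_px=896, pixel_size_um=4.0)


def small_config(**overrides) -> SimulationConfig:
    kwargs = dict(TEST_GEOMETRY)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def cohort():
    """Default-size synthetic cohort (31 cases) on the fast test geometry."""
    return generate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def cohort_features(cohort):
    cases, cellmaps, annotations = cohort
    cfg = RoiConfig(pixel_size_um=TEST_GEOMETRY["pixel_size_um"])
    table = extract_feature_table(cases, cellmaps, annotations, cfg)
    return table, clinical_frame(cases)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def planted_feature_table(rng, n=31, n_noise=113, resp_fraction=12 / 31,
                          mu_resp=6.0, mu_non=1.5, sigma=1.0):
    """One informative feature among permutation-style noise columns."""
    y = np.zeros(n, dtype=bool)
    y[: int(round(n * resp_fraction))] = True
    rng.shuffle(y)
    planted = np.where(y, rng.normal(mu_resp, sigma, n), rng.normal(mu_non, sigma, n))
    X = pd.DataFrame(
        rng.normal(size=(n, n_noise)), columns=[f"noise{i:03d}" for i in range(n_noise)]
    )
    X.insert(0, "planted", planted)
    X.index = [f"case{i:03d}" for i in range(n)]
    return X, y
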