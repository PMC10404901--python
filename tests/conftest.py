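"""Shared fixtures and simulation helpers for the test suite."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dyadisc import (
    SimulationConfig,
    double_rows,
    dyad_group,
    median_split,
    simulate_study,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_subjects=10, n_parcels=4, affected_parcels=(1, 2), n_runs=2,
        timepoints_per_run=120, attunement_slope=0.2, seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


def make_group_design(n_subjects: int, rng: np.random.Generator):
    """Canonical dyad table with AK group labels from random trait scores."""
    ids = list(range(1, n_subjects + 1))
    scores = pd.Series(rng.normal(16.0, 5.0, n_subjects), index=ids)
    status = median_split(scores)
    rows = [
        {
            "subject_a": a,
            "subject_b": b,
            "group": dyad_group(status[a], status[b]),
            "max_loneliness": max(scores[a], scores[b]),
        }
        for a, b in combinations(ids, 2)
    ]
    return pd.DataFrame(rows), status, scores


def simulate_dyadic_response(dyad_df: pd.DataFrame, group_means: dict,
                             var_subject: float, var_resid: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Unique-dyad responses from the crossed random-intercepts model."""
    ids = sorted(set(dyad_df["subject_a"]) | set(dyad_df["subject_b"]))
    a = dict(zip(ids, rng.normal(0.0, np.sqrt(var_subject), len(ids))))
    mu = dyad_df["group"].map(group_means).to_numpy()
    return (
        mu
        + dyad_df["subject_a"].map(a).to_numpy()
        + dyad_df["subject_b"].map(a).to_numpy()
        + rng.normal(0.0, np.sqrt(var_resid), len(dyad_df))
    )


def doubled_with_response(dyad_df: pd.DataFrame, y: np.ndarray):
    """Double the design and replicate the unique-dyad response."""
    doubled = double_rows(dyad_df)
    return doubled, np.concatenate([y, y])
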