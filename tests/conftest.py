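"""Shared fixtures: hand-built micro-cohorts and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vkproteome import BlockConfig, CohortDataset, SimConfig, generate_cohort

settings.register_profile("package", derandomize=True, deadline=None)
settings.load_profile("package")
from vkproteome.preprocess import log2_median_normalize


def make_subjects(rows):
    """rows: list of (child, experiment, channel, pivka)."""
    df = pd.DataFrame(rows, columns=["child_id", "experiment_id", "channel",
                                     "pivka2_ugL"])
    df["below_detection"] = df["pivka2_ugL"] < 0.001
    return df


def make_observations(rows):
    """rows: list of (gene, gi, child, experiment, value)."""
    return pd.DataFrame(rows, columns=["gene_symbol", "gi_accession",
                                       "child_id", "experiment_id", "value"])


@pytest.fixture
def tiny_raw_cohort() -> CohortDataset:
    """Two experiments x three children each, two proteins, raw intensities."""
    subjects = make_subjects([
        ("c1", "e1", 1, 1.31), ("c2", "e1", 2, 2.5), ("c3", "e1", 3, 0.9),
        ("c4", "e2", 1, 1.1), ("c5", "e2", 2, 3.0), ("c6", "e2", 3, 0.0005),
    ])
    obs = []
    rng = np.random.default_rng(42)
    for child, exp in subjects[["child_id", "experiment_id"]].itertuples(
            index=False):
        for gene, gi in (("PA", "111"), ("PB", "222")):
            obs.append((gene, gi, child, exp,
                        float(2.0 ** rng.normal(14.0, 0.5))))
    return CohortDataset(subjects, make_observations(obs), normalized=False)


def small_sim_config(**kwargs) -> SimConfig:
    """A quick-to-generate cohort for unit tests (not the study defaults)."""
    defaults = dict(n_children=96, n_experiments=16, plex_size=8,
                    n_proteins_total=60, mean_proteins_per_experiment=45.0,
                    n_covered_target=None, min_children=9,
                    driver_slopes=(1.0, -0.7),
                    correlated_block=BlockConfig(size=4, rho=0.8),
                    seed=7)
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale study cohort, shared across tests that only read it."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def normalized_default(default_cohort):
    dataset, truth = default_cohort
    normalized, _ = log2_median_normalize(dataset)
    return normalized, truth
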