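"""Shared fixtures: scenarios, composition-level cohorts, and one
event-level clustered cohort (scaled to 1,500 events/subject so the whole
suite stays fast; the statistical structure is scale-free)."""

import logging

import numpy as np
import pytest

from immunet.cluster import ClusteringConfig, SOMCluster, compute_frequencies
from immunet.preprocess import PreprocessConfig, preprocess_cohort, read_cohort
from immunet.simulate import (
    build_default_scenario,
    generate_cohort,
    simulate_frequency_table,
)

logging.getLogger("immunet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scenario():
    return build_default_scenario()


@pytest.fixture(scope="session")
def freq_cohort(scenario):
    """One composition-level discovery cohort (frequency table %, groups,
    clinical) drawn with the canonical seed."""
    rng = np.random.default_rng(0)
    return simulate_frequency_table(scenario, rng)


@pytest.fixture(scope="session")
def event_cohort(tmp_path_factory):
    """Event-level discovery cohort on disk, 1,500 events/subject."""
    sc = build_default_scenario(events_per_subject=1500, seed=0)
    outdir = tmp_path_factory.mktemp("cohort")
    generate_cohort(sc, outdir)
    return sc, outdir


@pytest.fixture(scope="session")
def pooled_events(event_cohort):
    _, outdir = event_cohort
    matrices, clinical = read_cohort(outdir / "events", outdir / "clinical.tsv")
    pooled = preprocess_cohort(matrices, PreprocessConfig(seed=1))
    return pooled, clinical


@pytest.fixture(scope="session")
def clustered(pooled_events):
    """Fitted SOM + metaclusters + mixed-cluster exclusion + frequencies."""
    pooled, clinical = pooled_events
    model = SOMCluster(pooled, ClusteringConfig(seed=0)).fit()
    freq, groups = compute_frequencies(model)
    return model, freq, groups, clinical
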