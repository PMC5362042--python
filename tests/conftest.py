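import numpy as np
import pytest

import mfcparc as mp


@pytest.fixture(scope="session")
def strong_cohort():
    """A compact two-cluster cohort with clear planted structure."""
    return mp.generate_cohort(
        mp.CohortConfig(
            n_subjects=16,
            n_seed_vertices=60,
            n_target_vertices=150,
            n_timepoints=100,
            rng_seed=42,
        )
    )


@pytest.fixture(scope="session")
def strong_matrices(strong_cohort):
    co = strong_cohort
    return [
        mp.seed_correlation_fmri(ts, co.seed_vertex_ids, co.target_vertex_ids)
        for ts in co.timeseries
    ]


@pytest.fixture(scope="session")
def noise_matrices():
    """Per-subject matrices from pure i.i.d. Gaussian time series."""
    rng = np.random.default_rng(7)
    seeds = np.arange(40)
    targets = 40 + np.arange(400)
    return [
        mp.seed_correlation_fmri(
            mp.SubjectTimeSeries(rng.standard_normal((440, 80)), f"noise-{i}"),
            seeds,
            targets,
        )
        for i in range(16)
    ]


def truth_parcellation(cohort):
    return mp.Parcellation(
        labels=cohort.truth_seed_labels,
        k=cohort.config.n_clusters,
        algorithm="truth",
        seed_vertex_ids=cohort.seed_vertex_ids,
    )
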