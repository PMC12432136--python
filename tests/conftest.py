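"""Shared fixtures: small seeded synthetic bundles and fitted charts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ibap import default_truth, simulate_cohort, simulate_expression, simulate_outcomes
from ibap.normative import adapt_study_offset, compute_deviation_scores, fit_reference_charts


@pytest.fixture(scope="session")
def truth():
    """Default ground truth with every downstream effect switched on."""
    return default_truth(
        seed=11,
        lam0=0.5,
        lam1=0.8,
        persistence_prob=0.85,
        ses_main=0.03,
        ses_ga_interaction=0.006,
        cognition_coupling=5.0,
    )


@pytest.fixture(scope="session")
def bundle(truth):
    """Two-timepoint cohort with expression and outcomes, modest size."""
    b = simulate_cohort(truth, n_term=120, n_preterm=80, n_timepoints=2)
    b.expression, b.marker_sets = simulate_expression(truth, genes_per_type=8, noise_sd=0.4)
    return simulate_outcomes(b, truth)


@pytest.fixture(scope="session")
def meta(bundle):
    return bundle.morphometry.drop_duplicates("subject_id").set_index("subject_id")


@pytest.fixture(scope="session")
def truth_profiles(bundle, truth):
    """Deviation profiles scored against the generating chart (no fit error)."""
    return compute_deviation_scores(truth.chart, bundle.morphometry, on_unknown_study="zero")


@pytest.fixture(scope="session")
def fitted_chart(bundle):
    chart = fit_reference_charts(bundle.morphometry, measure="CTh", seed=0)
    return adapt_study_offset(chart, bundle.morphometry, "synth")


@pytest.fixture(scope="session")
def fitted_profiles(fitted_chart, bundle):
    return compute_deviation_scores(fitted_chart, bundle.morphometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
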