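"""Shared fixtures: synthetic study worlds and the headline posterior fit.

The expensive MCMC fits are session-scoped so the recovery, convergence and
trajectory-geometry checks all reuse the same posterior.
"""

from dataclasses import replace

import numpy as np
import pytest

import eduslope as es
from eduslope.simulate import rescale_truth

# study design used by the recovery-scale checks: 4 birth cohorts x 2
# samples x 50 persons = 400 persons, 5 waves, 10% per-wave dropout;
# education drawn within the allowed range so no person is filtered out
# and the generating basis equals the analysis basis exactly.
RECOVERY_DESIGN = es.StudyDesign(
    cohort_birth_years=(1919, 1929, 1939, 1949),
    persons_per_cell=50,
    dropout_hazard=0.1,
    education_min=6,
)


def null_em_truth() -> es.TrueParameters:
    """Episodic-memory-like truth with no education effect on change."""
    em = es.betula_like_truth("em")
    return replace(
        em, gamma={**em.gamma, "LS x education": 0.0, "QS x education": 0.0}
    )


def make_world(design, truth, data_seed):
    """Generate + prepare one synthetic dataset; returns dict with the
    prepared data and the truth mapped onto the standardised scale."""
    data = es.generate(design, truth, seed=data_seed)
    prep = es.prepare(
        data, "em", es.PrepConfig(recompute_centers_from_data=True)
    )
    scaled = rescale_truth(truth, prep.baseline_mean, prep.baseline_sd)
    return {
        "data": data,
        "prepared": prep,
        "truth": truth,
        "scaled_truth": scaled,
        "truth_vector": es.truth_table(scaled),
    }


@pytest.fixture(scope="session")
def recovery_world():
    return make_world(RECOVERY_DESIGN, null_em_truth(), data_seed=101)


@pytest.fixture(scope="session")
def main_fit(recovery_world):
    """Headline fit at the full protocol: 4 chains x 2,000 post-warmup draws."""
    model = es.BayesianGrowthModel(
        n_chains=4, n_draws=2000, n_warmup=2000, random_state=202
    )
    model.fit_prepared(recovery_world["prepared"])
    return model


@pytest.fixture(scope="session")
def small_world():
    """A cheap dataset for unit tests that need a real but small fit."""
    design = es.StudyDesign(
        cohort_birth_years=(1924, 1944),
        persons_per_cell=30,
        dropout_hazard=0.1,
        education_min=6,
    )
    return make_world(design, null_em_truth(), data_seed=77)


@pytest.fixture(scope="session")
def small_fit(small_world):
    model = es.BayesianGrowthModel(
        n_chains=4, n_draws=400, n_warmup=400, random_state=88
    )
    model.fit_prepared(small_world["prepared"])
    return model
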