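"""Shared fixtures: the engineered gene locus and a small simulated cohort."""

from __future__ import annotations

import pytest

from enumap.pedsim.cohort import SimParams, simulate_cohort
from enumap.pedsim.fixture import make_duox2_like_fixture


@pytest.fixture(scope="session")
def fx():
    """The engineered multi-exon gene fixture (deterministic)."""
    return make_duox2_like_fixture()


SMALL_PARAMS = SimParams(
    n_markers=800,
    enu_mean=600.0,
    n_background_genes=60,
    n_shared_variants=20,
    missing_rate=0.0,
    error_rate=0.0,
    n_controls=12,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A noise-free cohort used by Mendelian-consistency and IO tests."""
    return simulate_cohort(SMALL_PARAMS, seed=11)
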