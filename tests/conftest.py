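"""Shared fixtures: reference and well-conditioned datasets plus their fits.

The heavy SAEM fits are session-scoped so the whole suite pays for each of
them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import salbupop as sp
from salbupop.data import DesignSpec
from salbupop.initials import nca_informed_initials

#: master seed of the reference simulate-and-refit experiment
MASTER_SEED = 20240630


@pytest.fixture(scope="session")
def ref_dataset() -> sp.PKDataset:
    """Default 32-subject virtual study simulated from the reference model."""
    return sp.simulate_dataset(
        sp.default_virtual_cohort(), sp.default_popmodel(), seed=MASTER_SEED
    )


@pytest.fixture(scope="session")
def ref_fit(ref_dataset) -> sp.FitResult:
    """Full-schedule SAEM refit of the reference dataset (NCA-informed
    starting values, standard errors and importance-sampled likelihood)."""
    init = nca_informed_initials(ref_dataset)
    return sp.fit_saem(
        ref_dataset, init, sp.SaemSettings(seed=MASTER_SEED, n_is=5000)
    )


# A well-conditioned two-compartment drug: both disposition phases and the
# absorption phase are visible on the sampling grid, so every parameter is
# identifiable (unlike the reference salbutamol values, whose peripheral
# compartment is nearly invisible).
WC_THETA = {"ka": 1.5, "cl": 5.0, "v1": 10.0, "q": 3.0, "v2": 20.0}


@pytest.fixture(scope="session")
def wc_model() -> sp.PopModel:
    return sp.PopModel(
        theta=dict(WC_THETA),
        omega={"ka": 0.2, "cl": 0.25, "v1": 0.15, "q": 0.2, "v2": 0.2},
        correlations={("ka", "q"): 0.3},
        a=0.05,
        b=0.10,
    )


@pytest.fixture(scope="session")
def wc_design() -> DesignSpec:
    return DesignSpec(
        times=(0.0, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24, 32, 48),
        dose_ug=600.0,
    )


@pytest.fixture(scope="session")
def wc_dataset(wc_model, wc_design) -> sp.PKDataset:
    return sp.simulate_dataset(
        sp.sample_cohort(n=32, seed=4), wc_model, wc_design, seed=202
    )


@pytest.fixture(scope="session")
def wc_fit(wc_dataset) -> sp.FitResult:
    init = nca_informed_initials(wc_dataset)
    return sp.fit_saem(
        wc_dataset,
        init,
        sp.SaemSettings(n_explore=300, n_smooth=300, seed=55, n_is=3000),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
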