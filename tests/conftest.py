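"""Shared fixtures: bench configuration and cached simulated acquisitions."""

from __future__ import annotations

import pytest

from ssaxs import (
    make_amyloid_template,
    make_pmma_template,
    radial_q_binning,
    simulate_histogram,
)
from ssaxs.config import build_run_config
from ssaxs.reduce import fine_config
from ssaxs.simulate import AcquisitionConfig


@pytest.fixture(scope="session")
def bench():
    """Default bench run configuration (offset-detector preset)."""
    return build_run_config()


@pytest.fixture(scope="session")
def unheated_hist(bench):
    """One 600 s unheated-amyloid syringe acquisition, seed 1 (~5e5 windowed)."""
    tpl = make_amyloid_template(variant="unheated")
    return simulate_histogram(tpl, bench.geometry, bench.spectrum, bench.acquisition, seed=1)


@pytest.fixture(scope="session")
def unheated_fine_profile(bench, unheated_hist):
    return radial_q_binning(unheated_hist, bench.geometry, fine_config(bench.reduction))


@pytest.fixture(scope="session")
def pmma_hist(bench):
    """PMMA-only phantom acquisition, 1200 s, seed 2."""
    acq = AcquisitionConfig(
        exposure=1200.0,
        sample_material="pmma",
        sample_thickness=10.0,
        sample_density=1190.0,
        seed=2,
    )
    return simulate_histogram(make_pmma_template(), bench.geometry, bench.spectrum, acq)
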