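import sys
import pathlib

import numpy as np
import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # tests/oracles.py

from octband.brbf import BRBFConfig
from octband.enums import GroupLabel, LayerName
from octband.synthetic_cohort import CohortSpec, generate_bscan, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (74/38/43 eyes, 6 scans, 7 layers)."""
    return generate_cohort(CohortSpec(rng_seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast protocol tests (30/15/18 eyes)."""
    spec = CohortSpec(
        n_eyes_per_group={
            GroupLabel.HEALTHY: 30,
            GroupLabel.DM: 15,
            GroupLabel.MDR: 18,
        },
        rng_seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def fast_brbf():
    """Short MCMC settings for tests that only need a working posterior."""
    return BRBFConfig(mcmc_iterations=1600, burn_in=500, thinning=2, rng_seed=0)


@pytest.fixture()
def flat_scan():
    """Noise-free, pit-free scan whose band thicknesses equal the latents."""
    latent = {
        l: (th, tr, 1.0)
        for l, th, tr in zip(
            LayerName,
            [40.0, 80.0, 35.0, 35.0, 95.0, 20.0, 19.36],
            [0.17, 0.13, 0.08, 0.09, 0.15, 0.11, 0.27],
        )
    }
    return generate_bscan(
        latent, 0, rng_seed=3, pit_depth=0.0, roughness_um=0.0, noise_sd=0.0
    )


@pytest.fixture()
def latent_features():
    return {
        l: (th, tr, fd)
        for l, th, tr, fd in zip(
            LayerName,
            [40.0, 80.0, 35.0, 35.0, 95.0, 20.0, 19.36],
            [0.17, 0.13, 0.08, 0.09, 0.15, 0.11, 0.27],
            [1.26, 1.18, 1.14, 1.16, 1.10, 1.08, 1.12],
        )
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
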