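"""Shared fixtures: survey layouts, synthetic datasets, and one shared fit.

The module-level fit fixtures run real MCMC on small simulated datasets and
are session-scoped so the sampler compiles and runs once for the whole
suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from msom import (
    DetectionArray,
    MCMCConfig,
    StudyLayout,
    reference_layout,
    reference_scenario,
)
from msom.simulate import generate_dataset


@pytest.fixture(scope="session")
def ref_layout() -> StudyLayout:
    return reference_layout()


@pytest.fixture()
def tiny_layout() -> StudyLayout:
    """3 sites, both plants, 1 replicate each: a 3 x 2 observed grid."""
    return StudyLayout(site_classes=("both",) * 3, replicates_per_plant=1)


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic community (15-taxon pool, reference-style truth).

    The seed yields a representative dataset: several observed taxa with a
    spread of detection counts, plus undetected pool members.
    """
    return generate_dataset(reference_scenario(n_taxa_pool=15, seed=41))


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Shared MCMC fit of the small community, with full z and GOF traces."""
    model = small_sim.model()
    return model.fit(
        MCMCConfig(n_chains=2, n_iterations=6_000, burn_in=2_000, thin=4, seed=9),
        store_z=True,
    )


@pytest.fixture()
def detection_array(tiny_layout) -> DetectionArray:
    y = np.zeros((2, 3, 2), dtype=np.int8)
    y[0, 0, 0] = 1
    y[0, 2, 1] = 1
    y[1, 1, 0] = 1
    return DetectionArray(
        y=y, layout=tiny_layout, taxa=("taxon_a", "taxon_b"), n_observed_taxa=2
    )
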