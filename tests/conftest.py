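from __future__ import annotations

import numpy as np
import pytest

import jia_claims as jc


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic cohort with an inflated onset hazard so that a few
    hundred cases exist at a small population size."""
    cfg = jc.GeneratorConfig(seed=7, n_population=40_000, onset_hazard_per_100k=80.0)
    bundle, truth = jc.generate_bundle(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_cohorts(small_sim):
    _, bundle, _ = small_sim
    prevalent, incident, flow = jc.build_cohorts(bundle)
    return prevalent, incident, flow


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
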