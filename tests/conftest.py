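"""Shared fixtures: small synthetic communities and pipeline runs.

Expensive fixtures are session-scoped; every stochastic fixture is seeded so
the suite is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from amplicomm.pipeline import PipelineConfig, run_synthetic
from amplicomm.synthetic import default_community_spec, generate


@pytest.fixture(scope="session")
def noiseless_spec():
    """Four samples, no errors, no chimeras, no contaminants, no QC failures."""
    return default_community_spec(
        seed=5, n_reads=800, error_rate=0.0, ambig_rate=0.0,
        chimera_rate=0.0, archaea_fraction=0.0, short_rate=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_run(noiseless_spec):
    out = []
    report = run_synthetic(noiseless_spec, PipelineConfig(seed=5), truth_out=out)
    reads, truth = out[0]
    return noiseless_spec, reads, truth, report


@pytest.fixture(scope="session")
def noisy_spec():
    """Chimeras and errors on, modest depth — for flagging/rescue metrics."""
    return default_community_spec(seed=3, n_reads=800, error_rate=0.01, chimera_rate=0.1)


@pytest.fixture(scope="session")
def noisy_data(noisy_spec):
    reads, truth = generate(noisy_spec)
    return noisy_spec, reads, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
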