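import numpy as np
import pandas as pd
import pytest

from respsig.matrix import ExpressionMatrix
from respsig.simulate import SimulationConfig, simulate_cohort_bundle


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A fast, fully-featured study configuration for end-to-end tests."""
    base = dict(
        seed=seed,
        n_probes_mouse=800,
        n_probes_human=1200,
        n_good=6,
        n_poor=6,
        n_intermediate=18,
        n_vehicle=6,
        n_patients=40,
        n_signal_probes=40,
        n_chips=3,
        conc_missing=2,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_cohort_bundle(small_config())


@pytest.fixture
def random_matrix():
    """Random expression matrix with detection p-values."""

    def make(n_probes=50, n_samples=8, seed=0, with_detp=True):
        rng = np.random.default_rng(seed)
        probes = pd.Index([f"p{i:03d}" for i in range(n_probes)], name="probe_id")
        samples = pd.Index([f"s{j:02d}" for j in range(n_samples)], name="sample_id")
        values = pd.DataFrame(
            rng.normal(8, 1, (n_probes, n_samples)), index=probes, columns=samples
        )
        detp = (
            pd.DataFrame(rng.random((n_probes, n_samples)), index=probes, columns=samples)
            if with_detp
            else None
        )
        return ExpressionMatrix(values, detp)

    return make
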