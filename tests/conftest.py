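import numpy as np
import pytest

from dyclust import (ExpressionSeries, GroupDesign, PipelineParams,
                     run_pipeline, simulate_group_dataset)


@pytest.fixture(scope="session")
def fast_params():
    return PipelineParams.fast()


@pytest.fixture(scope="session")
def time_grid():
    return np.linspace(0.0, 10.0, 64)


@pytest.fixture(scope="session")
def three_group_run(fast_params):
    """One full pipeline run on the 140-gene three-group design at
    noise 0.5, shared by integration-level checks."""
    ds = simulate_group_dataset(GroupDesign.three_group(0.5), seed=11)
    return ds, run_pipeline(ds, fast_params, seed=11)


@pytest.fixture(scope="session")
def dynamic_run(fast_params):
    """One run on the time-varying three-group design (noise sd 0.5)."""
    ds = simulate_group_dataset(GroupDesign.three_group_dynamic(0.5), seed=4)
    return ds, run_pipeline(ds, fast_params, seed=4)


def cosine_series(freq, t, phase=0.0, gene_id="g"):
    return ExpressionSeries(gene_id, np.cos(2 * np.pi * freq * t + phase), t)
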