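import warnings

import numpy as np
import pytest

from cadnet.cohort import CohortConfig, simulate_cohort
from cadnet.pipeline import RunConfig, cmd_develop, cmd_generate, cmd_verify


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (606 subjects, 405 features), seed 42."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort configuration for fast structural tests."""
    return CohortConfig(
        n_total=160, n_dev=130, n_train=90, n_val=40, n_verif=30,
        n_features=40, n_informative=5, n_blocks=8, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full desk-scale pipeline run (seed 42): generate -> develop -> verify.

    Session-scoped because the GA development phase is the expensive stage;
    every test that inspects the trained model or the blinded report shares
    this run.
    """
    out = tmp_path_factory.mktemp("run42")
    config = RunConfig(seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = cmd_generate(config, out)
        model = cmd_develop(config, out)
        report = cmd_verify(config, out)
    return {
        "config": config,
        "out": out,
        "manifest": manifest,
        "model": model,
        "report": report,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
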