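import numpy as np
import pytest

from revlearn import GenParams, ModelParams, TaskConfig, canonical_orders


@pytest.fixture(scope="session")
def orders():
    """The two canonical pseudorandom trial orders."""
    return list(canonical_orders())


@pytest.fixture(scope="session")
def seq(orders):
    return orders[0]


@pytest.fixture()
def instructed_params():
    return ModelParams.instructed(0.061, 0.943)


def recovery_gen(alpha: float, rho: float, seed: int, n_subjects: int = 20,
                 noise_sd: float = 0.25, **overrides) -> GenParams:
    """Generating conditions of the parameter-recovery harness.

    Moderate noise is half the mean EV slope; habituation and the
    non-learner mixture are off so the recovery question is bias and
    precision of the learning parameters under the assumed model.
    """
    kw = dict(model=ModelParams.instructed(alpha, rho), noise_sd=noise_sd,
              habituation_slope=0.0, p_nonlearner=0.0, n_subjects=n_subjects,
              seed=seed)
    kw.update(overrides)
    return GenParams(**kw)
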