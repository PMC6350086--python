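import numpy as np
import pytest

from pymslt import generate_baseline
from pymslt.intervention import defaults_from_config
from pymslt.pipeline import ModelInputs


@pytest.fixture(scope="session")
def ds():
    """Default synthetic baseline (seed 1), shared across the suite."""
    return generate_baseline(seed=1)


@pytest.fixture(scope="session")
def central_inputs(ds):
    """Model inputs at the packaged central parameter values."""
    cascade, effect, decay, costs = defaults_from_config()
    return ModelInputs(ds=ds, cascade=cascade, effect=effect,
                       decay=decay, costs=costs)


@pytest.fixture(scope="session")
def base_run(central_inputs):
    """One full paired life-table run at central values (base scenario)."""
    from pymslt import effect_profile, run_mslt
    i = central_inputs
    profile = effect_profile(i.ds, i.cascade, i.effect, i.decay)
    return run_mslt(i.ds, profile)


@pytest.fixture(scope="session")
def null_run(ds):
    """Paired run with a zero BMI-change profile (null intervention)."""
    from pymslt import run_mslt
    from pymslt.synthpop import N_AGES
    zero = np.zeros((N_AGES, 2, 2, N_AGES))
    return run_mslt(ds, zero)
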