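import numpy as np
import pandas as pd
import pytest

from gpif import default_spec, generate_population
from gpif.impute import finalize_completed
from gpif.outcome_models import DesignRecipe, FittedOutcomeModel


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def survey(spec):
    """Default survey draw with missingness and a small examination arm."""
    return generate_population(spec, 4_000, seed=101)


@pytest.fixture(scope="session")
def complete_data(spec):
    """Complete-data variant: full examination arm, no item nonresponse."""
    ds = generate_population(spec.complete(), 6_000, seed=202)
    return finalize_completed(ds)


@pytest.fixture(scope="session")
def big_complete_data(spec):
    ds = generate_population(spec.complete(), 20_000, seed=303)
    return finalize_completed(ds)


@pytest.fixture()
def toy_frame():
    """4-person closed population with equal weights."""
    return pd.DataFrame({"bmi": [20.0, 26.0, 30.0, 35.0],
                         "weight": [1.0, 1.0, 1.0, 1.0]})


@pytest.fixture()
def toy_model():
    """Frozen risk model expit(-3 + 0.1 BMI), bypassing fitting."""
    recipe = DesignRecipe(exposure="bmi", adjustment=[], levels={})
    return FittedOutcomeModel(outcome="diabetes", recipe=recipe,
                              params=np.array([-3.0, 0.1]),
                              names=["intercept", "bmi"],
                              cov=np.zeros((2, 2)), aic=0.0, n=4, weighted=True)
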