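import numpy as np
import pytest

import tgicomb as tg


@pytest.fixture(scope="session")
def c1_setup():
    """The first oral-drug/CPT-11 combination schedule with example PK/PD."""
    fx = tg.experiment_fixture("c1")
    pk = tg.example_pk_library(fx.drug_a, fx.drug_b)
    conc_a = tg.concentration_profile(pk[fx.drug_a], fx.regimen_a)
    conc_b = tg.concentration_profile(pk[fx.drug_b], fx.regimen_b)
    return {"fixture": fx, "pk": pk, "conc_a": conc_a, "conc_b": conc_b}


@pytest.fixture(scope="session")
def example_spec():
    return tg.example_model_spec(gamma=0.8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
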