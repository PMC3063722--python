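import warnings

import numpy as np
import pytest

from mnemodels import (
    FitOptions,
    SyntheticSpec,
    fit_reduced_models,
    gate_dataset,
    named_gate,
    simulate_neuron,
)

# exact-gate fits: near-zero shrinkage and a generous cap so deterministic
# tables are reached to high precision (the L2 bias on the matched moments
# is 2*lambda*|coef|, so it must sit well below the 1e-6 tolerance)
GATE_OPTS = FitOptions(l2_penalty=1e-10, coefficient_cap=500.0)


@pytest.fixture(scope="session")
def xor_data():
    return gate_dataset(named_gate("XOR"))


@pytest.fixture(scope="session")
def and_data():
    return gate_dataset(named_gate("AND"))


@pytest.fixture(scope="session")
def synthetic_run():
    """One shared large simulation (T=2e5 bins) with order-1/2 fits.

    Session-scoped because several recovery and diagnostic tests reuse
    the same planted-model experiment.
    """
    spec = SyntheticSpec(seed=7, duration_bins=200_000)
    data, truth = simulate_neuron(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        reports, fits = fit_reduced_models(
            truth["s1"], truth["s2"], data.responses, orders=(1, 2)
        )
    return {"spec": spec, "data": data, "truth": truth, "reports": reports, "fits": fits}
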