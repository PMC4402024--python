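import numpy as np
import pandas as pd
import pytest

import medpaths as mp

#: Closed-form path effects of the interaction-free fixture SEM:
#: direct 1.0, via-M1 0.5*0.6, via-M2 0.3*0.7, via-both 0.5*0.4*0.7.
POC_TRUTH = {"NDE": 1.0, "NIE1": 0.30, "NIE2": 0.21, "NIE12": 0.14}


@pytest.fixture(scope="session")
def poc_params():
    """Interaction-free SEM whose effects are products of coefficients."""
    return mp.TrueSEMParams.product_of_coefficients()


@pytest.fixture(scope="session")
def izhevsk_params():
    """The default interaction-bearing SEM fixture."""
    return mp.TrueSEMParams()


@pytest.fixture(scope="session")
def poc_dataset(poc_params):
    return mp.generate_observed(poc_params, 2000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(izhevsk_params):
    return mp.generate_observed(izhevsk_params, 500, seed=5)


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    specs = mp.default_specs(small_dataset, interactions=True)
    return {role: mp.fit_model(small_dataset, specs[role], role) for role in ("m1", "m2", "y")}


def clustered_se(table_a, table_b, contrast):
    """MC standard error of the difference of one contrast between two tables
    sharing subjects: per-subject means, SD / sqrt(n)."""
    plus, minus = contrast
    da = table_a.cells[plus] - table_a.cells[minus]
    db = table_b.cells[plus] - table_b.cells[minus]
    diff = (da - db).reshape(table_a.K, table_a.n_subjects).mean(axis=0)
    return float(diff.std(ddof=1) / np.sqrt(table_a.n_subjects))
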