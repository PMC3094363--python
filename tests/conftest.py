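import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from treecarb import AllometricEquation, DensityRecord
from treecarb.synthetic import LibrarySpec, TrueAllometry, generate_catalog

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def loglog_eq():
    """ln y = -2.0 + 2.4 ln D, biomass."""
    return AllometricEquation(
        id="ll1",
        species="sp",
        component="stem wood",
        response_kind="biomass",
        form_id="log-log",
        coefficients=(-2.0, 2.4),
        dev_min_cm=3.0,
        dev_max_cm=100.0,
        log_base_e=True,
        mse_log=0.1,
    )


@pytest.fixture
def linear_identity_eq():
    return AllometricEquation(
        id="lin1",
        species="sp",
        component="stem wood",
        response_kind="biomass",
        form_id="linear-combination",
        coefficients=(0.0, 1.0),
        dev_min_cm=1.0,
        dev_max_cm=100.0,
    )


def make_linear(eq_id, c0, c1, species="sp", component="stem wood", **kw):
    kw.setdefault("dev_min_cm", 1.0)
    kw.setdefault("dev_max_cm", 100.0)
    return AllometricEquation(
        id=eq_id,
        species=species,
        component=component,
        response_kind="biomass",
        form_id="linear-combination",
        coefficients=(c0, c1),
        **kw,
    )


def make_power(eq_id, a, b, species="sp", component="stem wood", **kw):
    kw.setdefault("dev_min_cm", 1.0)
    kw.setdefault("dev_max_cm", 100.0)
    return AllometricEquation(
        id=eq_id,
        species=species,
        component=component,
        response_kind="biomass",
        form_id="power",
        coefficients=(a, b),
        **kw,
    )


@pytest.fixture
def truth():
    return TrueAllometry.default(["Pseudotsuga menziesii", "Tsuga heterophylla"])


@pytest.fixture
def small_library(truth):
    """Small noisy catalog + densities covering the default roadmap leaves."""
    spec = LibrarySpec(n_equations=3, noise_sd=0.1)
    return generate_catalog(truth, spec, seed=42)


@pytest.fixture
def uniform_inventory():
    """120 trees per class at classes 10..20, expansion 1 (divisible by 10)."""
    classes = np.repeat(np.arange(10, 21), 120)
    return pd.DataFrame(
        {
            "species": "Pseudotsuga menziesii",
            "dbh_cm": classes.astype(float),
            "expansion_factor": 1.0,
        }
    )
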