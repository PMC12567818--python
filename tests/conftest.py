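"""Shared fixtures and the independent scalar (classical-model) oracle."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import dustrisk as dr

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def classical_intakes(c: float, p: dict, at: float) -> dict:
    """Scalar classical exposure model, coded independently of the package.

    *c* is the (bioaccessible) concentration in mg/kg; *p* holds crisp
    scalars IngR, InhR, BW, ED, EF, SA, SSAR, ABS, PEF; *at* is the
    averaging time in days.  Returns intakes per pathway in mg/(kg·d).
    """
    base = c * p["ED"] * p["EF"] / (p["BW"] * at)
    return {
        "ingestion": base * p["IngR"] * 1e-6,
        "inhalation": base * p["InhR"] / p["PEF"],
        "dermal": base * p["SA"] * p["SSAR"] * p["ABS"] * 1e-6,
    }


@pytest.fixture(scope="session")
def default_scenarios():
    return dr.load_scenarios()


@pytest.fixture(scope="session")
def default_tox():
    return dr.load_toxicity()


@pytest.fixture(scope="session")
def default_scheme():
    return dr.load_risk_scheme()


@pytest.fixture(scope="session")
def samples34():
    """Default calibrated synthetic campaign: 34 samples, 4 sites × 4 seasons."""
    return dr.generate_samples(dr.GeneratorConfig(seed=0))
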