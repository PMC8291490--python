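import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from gatingkit.schemes import OPEN, SHUT, Edge, KineticScheme, \
    make_builtin_scheme

#: identifiable wild-type-like rate set for round-trip tests (s^-1)
WT_LIKE_FJWM = dict(kon=8e6, koff=2000.0, delta2=1500.0, gamma2=300.0,
                    beta2=2500.0, alpha2=1100.0, d2=400.0, r2=20.0)

WT_LIKE_SC = dict(delta2=1500.0, gamma2=700.0, beta2=1500.0, alpha2=345.0,
                  beta2p=1000.0, alpha2p=1000.0, d2=50.0, r2=20.0)

SATURATING = 0.01  # 10 mM in molar


@pytest.fixture
def fjwm():
    return make_builtin_scheme("fJWM", rates=WT_LIKE_FJWM)


@pytest.fixture
def sc_oneD():
    return make_builtin_scheme("sc_oneD", rates=WT_LIKE_SC)


@pytest.fixture
def two_state_binding():
    """C<->O where opening requires agonist: relaxes from fully shut at
    zero agonist, with closed-form jump response."""
    return KineticScheme(
        name="CO-binding",
        states=["C", "O"],
        state_class={"C": SHUT, "O": OPEN},
        edges=[Edge("C", "O", "beta", conc_dep=True), Edge("O", "C", "alpha")],
        rates={"beta": 1e6, "alpha": 1000.0},
    )


def assert_rates_close(fitted: dict, truth: dict, rtol: float,
                       keys=None) -> None:
    keys = keys or truth.keys()
    for k in keys:
        assert fitted[k] == pytest.approx(truth[k], rel=rtol), (
            f"rate {k}: fitted {fitted[k]:.4g} vs truth {truth[k]:.4g}"
        )


def median_rate_error(fitted: dict, truth: dict, keys=None) -> float:
    keys = list(keys or truth.keys())
    return float(np.median([abs(fitted[k] / truth[k] - 1.0) for k in keys]))
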