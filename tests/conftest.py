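import numpy as np
import pytest

import stochzyme as sz


@pytest.fixture
def fig5a_scheme():
    """Two-state catalysis, published constants (uncompetitive)."""
    return sz.get_fixture("fig5a").scheme


@pytest.fixture
def markovian_uncompetitive():
    """All-exponential uncompetitive scheme (classical limit)."""
    return sz.InhibitionScheme(
        mode="uncompetitive",
        k_on=0.1,
        T_cat=sz.make_exponential(0.1),
        T_off=sz.make_exponential(2.3),
        k_on_ESI=3.0,
        T_off_ESI=sz.make_exponential(10.0),
    )


@pytest.fixture
def all_families():
    """One representative of each distribution family, comparable scales."""
    return [
        sz.make_exponential(1.0),
        sz.make_hyperexponential2(0.1, 50.0, 0.5),
        sz.make_gamma(4.0, 0.25),
        sz.make_moment_matched("weibull", 2.0, 1.5),
        sz.make_moment_matched("lognormal", 2.0, 1.5),
    ]


def quadrature_mean(d, upper=None):
    """Independent moment oracle: mean = ∫ survival."""
    from scipy.integrate import quad

    hi = upper if upper is not None else d.isf(1e-13)
    val, _ = quad(lambda t: float(d.sf(t)), 0, hi, limit=300)
    return val


def quadrature_moment(d, order):
    """Independent oracle: raw moment via ∫ t^n f(t) dt."""
    from scipy.integrate import quad

    hi = d.isf(1e-13)
    val, _ = quad(lambda t: t**order * float(d.pdf(t)), 0, hi, limit=300)
    return val
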