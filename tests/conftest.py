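import numpy as np
import pytest

from redoxswitch import INVENTORIES, PRESETS, RateSet, build_switch_network, simulate


@pytest.fixture
def ph7():
    return PRESETS["ph7"]


@pytest.fixture
def ph9():
    return PRESETS["ph9"]


@pytest.fixture
def rabbit():
    return INVENTORIES["rabbit"]


@pytest.fixture
def completed_run(ph7, rabbit):
    """Variant-(i) oxidation run to completion at working concentrations."""
    net = build_switch_network(ph7.rates, rabbit, "i")
    t = np.linspace(0.0, 3600.0, 200)
    traj = simulate(net, {"H2O2": ph7.h2o2_0, "E_red": ph7.subunit_conc}, t)
    return traj, ph7


@pytest.fixture
def pseudo_first_order_run():
    """Large H2O2 excess, no side branch: the analytic consecutive regime.

    Tiny enzyme against 1 M oxidant keeps the pseudo-first-order
    approximation itself below the comparison tolerance."""
    rates = RateSet.default(9.4, h2o2=1.0, k_side=0.0)
    net = build_switch_network(rates, INVENTORIES["rabbit"], "i")
    e0 = 1e-8
    t = np.linspace(0.0, 3.0 / 9.4, 60)
    traj = simulate(net, {"H2O2": 1.0, "E_red": e0}, t, rtol=1e-10, atol=1e-18)
    return traj, e0, 9.4
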