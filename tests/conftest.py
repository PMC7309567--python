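import numpy as np
import pytest

from ivlsim.channels import ChannelSet, ChannelSpec, GatingScheme
from ivlsim.morphology import CompartmentGeometry, Morphology


@pytest.fixture(scope="session")
def cell1():
    from ivlsim.fixtures import make_reference_cell
    return make_reference_cell(1)


@pytest.fixture(scope="session")
def cell2():
    from ivlsim.fixtures import make_reference_cell
    return make_reference_cell(2)


@pytest.fixture()
def single_passive():
    """One 20x20 um passive compartment with 1 pS/um^2 leak at -70 mV."""
    comp = CompartmentGeometry(length=20.0, diameter=20.0)
    morph = Morphology([comp], np.array([-1]), ["soma"], {"S": 0})
    specs = {"leak": ChannelSpec("leak", -70.0, GatingScheme(0, 0))}
    channels = ChannelSet(specs, {"leak": {"soma": 1.0}})
    g_us = 1.0 * comp.area * 1e-6
    c_nf = 1.0 * comp.area * 1e-5
    return morph, channels, {"g_us": g_us, "c_nf": c_nf,
                             "tau_ms": c_nf / g_us, "r_in_mohm": 1.0 / g_us}


def passive_chain(n=50, length=8.0, diameter=2.0, leak=0.05, e_leak=-70.0,
                  ra=150.0):
    """Uniform passive cable: soma-sized stub plus n dendritic compartments."""
    comps = [CompartmentGeometry(length=length, diameter=diameter,
                                 axial_resistivity=ra)]
    parents = [-1]
    regions = ["soma"]
    for i in range(n):
        comps.append(CompartmentGeometry(length=length, diameter=diameter,
                                         axial_resistivity=ra))
        parents.append(i)
        regions.append("dend")
    morph = Morphology(comps, np.array(parents), regions, {"S": 0})
    specs = {"leak": ChannelSpec("leak", e_leak, GatingScheme(0, 0))}
    channels = ChannelSet(specs, {"leak": {"soma": leak, "dend": leak}})
    return morph, channels
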