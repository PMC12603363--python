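import numpy as np
import pytest

from oakleaf.gas_exchange import AciCurve, FvcbParams
from oakleaf.synthetic import SimSpec, full_protocol_setpoints, simulate_aci


def make_curve(ci, an, **kwargs):
    """AciCurve from bare (ci, an) arrays; other columns filled with defaults."""
    ci = np.asarray(ci, dtype=float)
    an = np.asarray(an, dtype=float)
    defaults = dict(
        ca_setpoint=ci + 40.0, ci=ci, an=an,
        gs=np.full(ci.size, 0.3), ppfd=np.full(ci.size, 1500.0),
        leaf_temp=np.full(ci.size, 30.0),
    )
    defaults.update(kwargs)
    return AciCurve(**defaults)


@pytest.fixture
def identifiable_params():
    """Parameter set for which all three FvCB limitations bind on the
    13-setpoint protocol (Rubisco at low Cc, RuBP regeneration in the
    mid range, TPU at the top)."""
    return FvcbParams(vcmax=100.0, jmax=150.0, tpu=11.0, rd=1.0, gm=0.25)


@pytest.fixture
def noiseless_curve(identifiable_params):
    spec = SimSpec(params=identifiable_params,
                   ca_setpoints=full_protocol_setpoints(), noise_sd=0.0)
    return simulate_aci(spec)[0]
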