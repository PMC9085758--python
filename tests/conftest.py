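import numpy as np
import pytest

from mesocell.models import PhosphoParams, build_signalosome


@pytest.fixture(scope="session")
def phospho_params():
    return PhosphoParams()


@pytest.fixture(scope="session")
def signalosome(phospho_params):
    """Generated PKA/AQP2 network (no SRC arm), shared across tests."""
    net, simples = build_signalosome(phospho_params)
    return net


@pytest.fixture(scope="session")
def signalosome_src(phospho_params):
    """Generated network including the CSK/SRC inhibition cascade."""
    net, simples = build_signalosome(phospho_params, include_src=True)
    return net


def dense_rhs_oracle(net, influx_label=None, influx=0.0):
    """Independent dense ODE right-hand side assembled from the flat
    reaction list (stoichiometric matrix times mass-action rates)."""
    labels = sorted(net.entities)
    idx = {lab: k for k, lab in enumerate(labels)}
    terms = []
    for rx in net.reactions:
        k = dict(rx.rate_constants)["k"]
        S = np.zeros(len(labels))
        for s in rx.substrates:
            S[idx[s]] -= 1
        for s in rx.products:
            S[idx[s]] += 1
        terms.append((k, [idx[s] for s in rx.substrates], S))

    def f(t, y):
        out = np.zeros_like(y)
        for k, si, S in terms:
            v = k
            for i in si:
                v = v * y[i]
            out += S * v
        if influx_label is not None:
            out[idx[influx_label]] += influx
        return out

    return f, idx
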