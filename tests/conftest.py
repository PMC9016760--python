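import numpy as np
import pytest
import scipy.sparse as sp

from fluxdesign.fixtures import chain_model, toy_fig1_network
from fluxdesign.model import MetabolicModel


@pytest.fixture(scope="session")
def fig1():
    """(model, FS_w, FS_m) for the five-reaction branch-point network."""
    return toy_fig1_network()


@pytest.fixture()
def chain4():
    return chain_model(4)


@pytest.fixture()
def parallel_routes_model():
    """Two equivalent internal routes sharing uptake capacity 10."""
    S = sp.csc_matrix(np.array([
        # UPT  A1   A2   BIO
        [1.0, -1.0, -1.0, 0.0],   # M0
        [0.0, 1.0, 1.0, -1.0],    # M1
    ]))
    return MetabolicModel(
        metabolite_ids=["M0", "M1"],
        reaction_ids=["UPT", "ROUTE_A", "ROUTE_B", "BIO"],
        S=S,
        lb=np.zeros(4),
        ub=np.array([10.0, 10.0, 10.0, 10.0]),
        biomass_id="BIO",
        exchange_ids=["UPT"],
    )
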