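import numpy as np
import pytest

from spatstar.graph import make_lattice
from spatstar.model import StructuredAdditiveLogit
from spatstar.simulate import rwanda_like_config, simulate_survey

FIXED_TERMS = ("decisions", "wealth", "controlling", "alcohol")


@pytest.fixture(scope="session")
def lattice30():
    return make_lattice(5, 6)


@pytest.fixture(scope="session")
def women_data(lattice30):
    """One women-like survey realisation with ground truth."""
    cfg = rwanda_like_config("women", graph=lattice30, seed=20259)
    return simulate_survey(cfg), cfg


@pytest.fixture(scope="session")
def women_fit(women_data):
    """A single fit of the full spatial model on the women-like data,
    shared across tests that inspect different aspects of the posterior."""
    ds, cfg = women_data
    est = StructuredAdditiveLogit(
        fixed=FIXED_TERMS, smooth=("age",), graph=cfg.graph,
        n_iter=3000, burn_in=500, thin=2, n_chains=2, seed=7,
    )
    est.fit(ds.records)
    return est


def true_coefs(cfg):
    """Flatten the generating fixed effects into (term, level) -> log-odds."""
    out = {}
    for term, eff in cfg.fixed_effects.items():
        for lv, v in eff.items():
            out[(term, lv)] = float(v)
    return out
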