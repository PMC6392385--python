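import numpy as np
import pytest

from miteabc.coalsim import LabeledAlignment
from miteabc.scenarios import ParameterDraw, PriorSet


@pytest.fixture
def rng():
    return np.random.default_rng(20190124)


@pytest.fixture
def priors():
    return PriorSet()


def make_draw(scenario_id=2, **overrides) -> ParameterDraw:
    vals = {
        "N_LW": 1000.0,
        "N_ML": 2000.0,
        "N_HG": 1500.0,
        "t1": 100.0,
        "t2": 500.0,
        "r": 0.5,
        "mu": 1e-6,
        "kappa": 2.0,
    }
    vals.update(overrides)
    return ParameterDraw(scenario_id, vals)


def random_alignment_matrix(rng, n_rows=20, n_sites=100, missing_frac=0.0):
    m = rng.integers(0, 4, size=(n_rows, n_sites)).astype(np.int8)
    # sprinkle shared variation so sites are not all singletons
    for _ in range(n_sites // 4):
        col = rng.integers(n_sites)
        base = rng.integers(0, 4)
        rows = rng.choice(n_rows, size=rng.integers(2, n_rows), replace=False)
        m[rows, col] = base
    if missing_frac > 0:
        mask = rng.random(m.shape) < missing_frac
        m[mask] = -1
    return m


@pytest.fixture
def tiny_alignment():
    """Six sequences, two per form, with hand-countable variation."""
    seqs = [
        "ACGTACGT",
        "ACGTACGA",
        "ACGTTCGT",
        "ACGTTCGT",
        "ACCTTCGT",
        "ACCTTCGT",
    ]
    ids = [f"p{i}" for i in range(6)]
    forms = ["LW", "LW", "ML", "ML", "HG", "HG"]
    return LabeledAlignment(ids=ids, forms=forms, sequences=seqs)
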