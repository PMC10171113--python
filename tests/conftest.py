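import numpy as np
import pandas as pd
import pytest

from carcinoscope import miniature_genome
from carcinoscope.mutsig import build_context_matrix
from carcinoscope.refsigs import synthetic_cosmic_v2_like
from carcinoscope.simcohort import simulate_mutation_catalog


@pytest.fixture(scope="session")
def genome():
    return miniature_genome()


@pytest.fixture(scope="session")
def refs():
    return synthetic_cosmic_v2_like()


@pytest.fixture(scope="session")
def four_signature_cohort(refs):
    """15 samples drawn from four planted signatures (MSI / APOBEC /
    BRCAness / clock families), with the planted exposure matrix."""
    use = ["Signature 6", "Signature 2", "Signature 3", "Signature 1"]
    rng = np.random.default_rng(0)
    cols, exposures = [], {}
    for s in range(15):
        name = f"P{s:02d}"
        e = rng.dirichlet(np.ones(4) * 0.8)
        exposures[name] = dict(zip(use, e))
        muts = simulate_mutation_catalog(exposures[name], 5000, refs,
                                         seed=1000 + s, sample=name)
        cols.append(build_context_matrix(muts)[name])
    return pd.concat(cols, axis=1), refs[use], exposures
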