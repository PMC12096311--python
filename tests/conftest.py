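import numpy as np
import pytest

from svrefine.evaluator import PRESETS, match_calls
from svrefine.pipeline import curate_genomes
from svrefine.synthetic import scenario_suite


def make_rng(seed=0):
    return np.random.default_rng(seed)


def random_seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def suite():
    """The full noiseless scenario suite (deterministic)."""
    return scenario_suite(1)


@pytest.fixture(scope="session")
def curation(suite):
    """Pipeline result on the noiseless suite."""
    return curate_genomes(suite.ref_genomes, suite.qry_genomes, suite.calls)


@pytest.fixture(scope="session")
def strict_eval(suite, curation):
    return match_calls(curation.svs, suite.valid_truths, PRESETS["strict"])
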