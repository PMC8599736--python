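import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cleavemap import ERROR_FREE, build_consensus, build_plasmid, call_read, emit_concatemer, estimate_period
from cleavemap.caller import CallerParams
from cleavemap.fixtures import geometry_enzymes, toy_fixtures
from cleavemap.io import FastqRead


@pytest.fixture(scope="session")
def toy():
    return toy_fixtures()


@pytest.fixture(scope="session")
def ref(toy):
    return toy[0]


@pytest.fixture(scope="session")
def cassette(toy):
    return toy[1]


@pytest.fixture(scope="session")
def enzymes(ref):
    return geometry_enzymes(ref)


@pytest.fixture(scope="session")
def params():
    return CallerParams()


@pytest.fixture
def roundtrip(ref, cassette, params):
    """Simulate one event end-to-end (error-free) and call it."""

    def run(nicks, orientation="+", strand="+", repeats=3, rotation=777, err=ERROR_FREE, seed=0):
        rng = np.random.default_rng(seed)
        plasmid, truth = build_plasmid(ref, nicks, cassette, orientation=orientation)
        seq, qual = emit_concatemer(plasmid, repeats, rotation, strand, err, rng)
        read = FastqRead("rt", seq, qual)
        cread = build_consensus(read, estimate_period(read))
        call = call_read(cread, ref, cassette, params)
        return call, truth, plasmid

    return run
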