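"""Repeat-cutoff sweep: calling accuracy vs data retention.

Simulates an XmnI-type library with the default error model, calls every
read, and sweeps the repeat cutoff.  The five-adenine junction run makes
this site homopolymer-fragile: 1-3 bp contractions of the run are the
dominant miscalls and fade as the cutoff rises.
"""

import numpy as np

from cleavemap import (
    CallerParams,
    EnzymeModel,
    ErrorModel,
    build_consensus,
    call_library,
    cutoff_sweep,
    enzyme_nicks,
    estimate_period,
    simulate_library,
    toy_fixtures,
)
from cleavemap.fixtures import XMN_POS
from cleavemap.io import FastqRead

ref, cassette = toy_fixtures()
[nicks] = enzyme_nicks(EnzymeModel("xmn_like", "GAANNNNTTC", 5, 5), ref)
reads, _ = simulate_library(
    ref, cassette, [nicks] * 150, ErrorModel(), np.random.default_rng(4)
)
creads = []
for rid, seq, qual in reads:
    read = FastqRead(rid, seq, qual)
    c = build_consensus(read, estimate_period(read))
    if c is not None:
        creads.append(c)

calls, _ = call_library(creads, ref, cassette, CallerParams())
expected = (XMN_POS + 5, XMN_POS + 5)  # blunt cut mid-site
print(cutoff_sweep(calls, expected).to_string(index=False))
# accuracy = correct OK calls / OK calls in the stratum; retention = the
# fraction of all calls surviving the cutoff. Raising the cutoff trades
# data for accuracy.
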