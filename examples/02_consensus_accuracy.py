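"""Collapse concatemer reads into consensus sequences and score accuracy.

More tandem repeats per read mean more votes per column and a more
accurate consensus — the basis of repeat-cutoff filtering.
"""

import numpy as np

from cleavemap import ErrorModel, build_consensus, emit_concatemer, estimate_period, identity_vs_reference, toy_fixtures
from cleavemap.io import FastqRead

ref, _ = toy_fixtures()
rng = np.random.default_rng(1)
err = ErrorModel()  # 1% sub, 0.5% ins, 1% del, homopolymer deletions x5

print("repeats  raw_read_bp  consensus_identity_%")
for repeats in (1, 3, 5, 10):
    seq, qual = emit_concatemer(ref.seq, repeats, 100, "+", err, rng)
    read = FastqRead(f"R{repeats}", seq, qual)
    cons = build_consensus(read, estimate_period(read))
    ident = identity_vs_reference(cons, ref)
    print(f"{cons.repeats:7d}  {len(seq):11d}  {ident:8.2f}")
# identity is matches / alignment columns against the best rotation and
# strand of the circular reference; it climbs toward 100% with repeats.
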