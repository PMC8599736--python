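"""Simulate a single-cleavage-event library as concatemer reads.

Builds the toy circular substrate and dT-tailed marker cassette, cuts at
the XmnI-type site (GAANN|NNTTC, blunt), and emits rolling-circle
concatemer reads with a nanopore-like error model plus a truth table.
"""

import numpy as np

from cleavemap import EnzymeModel, ErrorModel, enzyme_nicks, simulate_library, toy_fixtures

ref, cassette = toy_fixtures()
[nicks] = enzyme_nicks(EnzymeModel("xmn_like", "GAANNNNTTC", 5, 5), ref)
print(f"substrate {ref.name}: {ref.L} bp, cut at bonds {sorted(nicks.top)}/{sorted(nicks.bottom)}")

reads, truth = simulate_library(
    ref, cassette, [nicks] * 10, ErrorModel(), np.random.default_rng(0)
)
print(f"emitted {len(reads)} concatemer reads, "
      f"mean length {np.mean([len(s) for _, s, _ in reads]):.0f} bp")
print(truth.head(3).to_string(index=False))
# reported_top/bottom are the nick bonds end repair preserves; repeats is
# the number of tandem template copies in each read.
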