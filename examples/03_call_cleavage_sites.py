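"""Call linked nick pairs from consensus reads and tabulate frequencies.

Events from a Cas12a-like model (fixed target-strand nick, variable
non-target-strand nick) are ligated, called, and summarised as a
site-frequency table and strand-linkage marginals.
"""

import numpy as np

from cleavemap import (
    CallerParams,
    ConsensusRead,
    EventDistribution,
    build_plasmid,
    call_library,
    sample_events,
    site_frequencies,
    slp,
    toy_fixtures,
)

ref, cassette = toy_fixtures()
dist = EventDistribution(
    top_dist={980: 0.6, 975: 0.2, 973: 0.12, 985: 0.08},  # variable NTS nick
    bottom_dist={1000: 1.0},  # invariant TS nick
)
events = sample_events(dist, 300, np.random.default_rng(2))
creads = []
for i, ev in enumerate(events):
    plasmid, _ = build_plasmid(ref, ev, cassette)
    creads.append(ConsensusRead(f"ev{i}", plasmid, 5, 20.0, len(plasmid)))

calls, summary = call_library(creads, ref, cassette, CallerParams())
print("status summary:", dict(summary))
print(site_frequencies(calls).to_string(index=False))
mat = slp(calls, window=(970, 1001))
print("top-strand marginal:", dict(mat.top_marginal[mat.top_marginal > 0]))
# each row links one top-strand nick bond to its bottom-strand partner;
# the overhang sign follows d = bottom - top (positive = 5' overhang).
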