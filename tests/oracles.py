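"""Independent oracles used by the test suite (and the acceptance script).

These deliberately share no logic with the package implementation: the
repair oracle manipulates explicit per-strand base lists, and the
collision oracle enumerates every walker path.
"""

from __future__ import annotations

import numpy as np


def repair_oracle(top_nicks, bottom_nicks, L: int):
    """Base-by-base end-repair simulation on a circular duplex.

    Cuts both strands at the given bonds, keeps the largest fragment
    (internal fragments between nicks are lost during cloning), then
    repairs both ends: a recessed 3' terminus is filled in up to the
    partner strand's 5' terminus (5'-overhang fill-in) and a protruding
    3' terminus is chewed back to it (3'-overhang removal).  Returns the
    blunt end bonds as ``(reported_top, reported_bottom)`` where
    ``reported_top`` is the bond at which the repaired top strand starts
    and ``reported_bottom`` the bond at which it ends.

    Assumes all nicks fall in one locus window much smaller than ``L``
    (the exhaustive tests construct them that way).
    """
    tops = sorted(set(int(b) % L for b in top_nicks))
    bots = sorted(set(int(b) % L for b in bottom_nicks))
    if not tops or not bots:
        raise ValueError("need at least one nick per strand")

    # localise the window: order nicks along the arc that avoids the
    # largest gap between any two consecutive nick bonds
    bonds = sorted(set(tops) | set(bots))
    gaps = [((bonds[(i + 1) % len(bonds)] - bonds[i]) % L, i) for i in range(len(bonds))]
    _, widest = max(gaps)
    w0 = bonds[(widest + 1) % len(bonds)]
    local = lambda b: (b - w0) % L

    # the recovered (largest) fragment runs the long way round the circle:
    # top strand from the last top nick bond to the first, bottom strand
    # (in top coordinates) from the last bottom nick bond to the first
    t_first = min(tops, key=local)
    t_last = max(tops, key=local)
    b_first = min(bots, key=local)
    b_last = max(bots, key=local)
    top_bases = [(t_last + i) % L for i in range(((t_first - t_last) % L) or L)]
    bot_bases = [(b_last + i) % L for i in range(((b_first - b_last) % L) or L)]

    # --- end repair, upstream end (3' end of the top strand) ---
    # top 3' terminus sits after base top_bases[-1]; bottom 5' terminus
    # after (in top coords) bot_bases[-1]
    while True:
        t_end = (top_bases[-1] + 1) % L
        b_end = (bot_bases[-1] + 1) % L
        if t_end == b_end:
            break
        if local(b_end) > local(t_end):
            top_bases.append(t_end)  # fill: extend recessed top 3' end
        else:
            top_bases.pop()  # trim: chew back protruding top 3' end
    # --- end repair, downstream end (3' end of the bottom strand) ---
    while True:
        t_start = top_bases[0] % L
        b_start = bot_bases[0] % L
        if t_start == b_start:
            break
        if local(b_start) > local(t_start):
            bot_bases.insert(0, (b_start - 1) % L)  # fill recessed bottom 3' end
        else:
            bot_bases.pop(0)  # trim protruding bottom 3' end
    reported_top = top_bases[0] % L
    reported_bottom = (top_bases[-1] + 1) % L
    return reported_top, reported_bottom


def collision_walk_pmf(d: int) -> np.ndarray:
    """Meeting-point distribution of two converging unit-step walkers.

    Walker A starts at 0 moving right, walker B at ``d`` moving left; at
    each tick one of the two (chosen with probability 1/2) takes a step.
    Every path is enumerated recursively until the walkers meet.
    """
    out = np.zeros(d + 1)

    def walk(a: int, b: int, prob: float) -> None:
        if a == b:
            out[a] += prob
            return
        walk(a + 1, b, prob / 2.0)
        walk(a, b - 1, prob / 2.0)

    walk(0, d, 1.0)
    return out
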