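"""Generative models of single cleavage-event libraries.

This module reproduces, in sequence space, the molecular steps that turn a
double-strand break on a circular substrate into a sequencing-ready
concatemer read:

1. an endonuclease nicks each strand one or more times (``enzyme_nicks``,
   ``sample_events``);
2. end repair blunts the recovered fragment — 5' overhangs are filled in,
   3' overhangs are removed — so only the nick closest to the 3' end of
   each strand survives into the cloned junction (``resolve_repair``);
3. a single non-templated adenine is added to each 3' end and a marker
   cassette carrying single 3' thymine overhangs is ligated, re-circularising
   the molecule (``build_plasmid``);
4. rolling-circle amplification produces a tandem-repeat concatemer that is
   read with substitution/indel errors, with deletions up-weighted inside
   homopolymer runs (``emit_concatemer``).

All coordinates are the bond indices of :mod:`cleavemap.seqcore`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import CircularRef, circ_delta, revcomp

__all__ = [
    "EnzymeModel",
    "NickSet",
    "EventDistribution",
    "CollisionModel",
    "ErrorModel",
    "CassetteSpec",
    "UnlinkedNicksError",
    "RejectedEventError",
    "enzyme_nicks",
    "resolve_repair",
    "build_plasmid",
    "sample_events",
    "apply_errors",
    "emit_concatemer",
    "simulate_library",
]


class UnlinkedNicksError(ValueError):
    """Nicks spread beyond the linkage window: no single repairable locus."""


class RejectedEventError(ValueError):
    """The break destroys too much of the substrate to yield a viable clone."""


@dataclass(frozen=True)
class EnzymeModel:
    """Fixed cleavage geometry of a site-specific endonuclease.

    Cut offsets are bond indices relative to the start of a '+' strand
    recognition match; for matches on the '-' strand the geometry is
    mirrored automatically.
    """

    name: str
    recognition: str
    top_cut_offset: int
    bottom_cut_offset: int

    def __post_init__(self) -> None:
        m = len(self.recognition)
        for off in (self.top_cut_offset, self.bottom_cut_offset):
            if not -20 <= off <= m + 20:
                raise ValueError(f"cut offset {off} outside [-20, {m + 20}]")


@dataclass(frozen=True)
class NickSet:
    """Strand-specific nick positions of one cleavage event (bond indices)."""

    top: frozenset
    bottom: frozenset

    def __init__(self, top, bottom):
        object.__setattr__(self, "top", frozenset(int(x) for x in top))
        object.__setattr__(self, "bottom", frozenset(int(x) for x in bottom))
        if not self.top or not self.bottom:
            raise ValueError("a double-strand break needs >=1 nick on each strand")


@dataclass
class EventDistribution:
    """Discrete generative model of where the two strand nicks fall.

    Either ``joint_pairs`` (an explicit table over (top, bottom) bond
    pairs) or ``top_dist`` plus ``bottom_dist`` must be given.
    ``bottom_dist`` may be a plain table, or a mapping from top-nick bond
    to a table (bottom conditional on top).
    """

    top_dist: dict | None = None
    bottom_dist: dict | None = None
    joint_pairs: dict | None = None

    def __post_init__(self) -> None:
        if self.joint_pairs is not None:
            _check_probs(self.joint_pairs.values())
        else:
            if self.top_dist is None or self.bottom_dist is None:
                raise ValueError("need joint_pairs, or top_dist and bottom_dist")
            _check_probs(self.top_dist.values())
            first = next(iter(self.bottom_dist.values()))
            if isinstance(first, dict):
                for tbl in self.bottom_dist.values():
                    _check_probs(tbl.values())
            else:
                _check_probs(self.bottom_dist.values())


def _check_probs(values) -> None:
    total = float(sum(values))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {total}, expected 1")


@dataclass
class CollisionModel:
    """Two convergent translocases initiate ``d`` steps apart and collide.

    Each elementary step is taken by one of the two motors with equal
    probability, so the collision point ``n`` (steps travelled by the
    first motor, ``0 <= n <= d``) follows the binomial law
    ``P(n) = d! / (n! (d-n)! 2^d)``.  After collision the complex nicks
    the top strand on one side and the bottom strand on the other while
    diffusing outwards; the half-spacing between collision point and each
    nick is ``min_half_spacing + Geometric(spread_p) - 1`` bonds.

    ``spread_p`` stands in for reaction time: earlier time points are
    modelled with larger ``spread_p`` (tighter nicks).  In ``symmetric``
    mode one half-spacing per event is applied to both sides, preserving
    the event midpoint exactly; ``independent`` mode draws one per strand.
    ``dissociation`` is the per-step probability that the stepping motor
    detaches and re-initiates at its start site, producing off-centre
    collisions.
    """

    d: int
    origin: int = 0
    spread_p: float = 0.5
    min_half_spacing: int = 15
    mode: str = "symmetric"
    dissociation: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("site separation d must be >= 1")
        if not 0.0 < self.spread_p <= 1.0:
            raise ValueError("spread_p must be in (0, 1]")
        if self.mode not in ("symmetric", "independent"):
            raise ValueError(f"unknown spread mode {self.mode!r}")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base read error rates with elevated homopolymer deletions.

    ``homopolymer_deletion_multiplier`` scales the deletion rate inside
    homopolymer runs of length >= 3, the dominant nanopore failure mode.
    """

    substitution: float = 0.01
    insertion: float = 0.005
    deletion: float = 0.01
    homopolymer_deletion_multiplier: float = 5.0

    def __post_init__(self) -> None:
        for r in (self.substitution, self.insertion, self.deletion):
            if not 0.0 <= r < 0.5:
                raise ValueError("error rates must lie in [0, 0.5)")
        if self.homopolymer_deletion_multiplier < 1.0:
            raise ValueError("homopolymer multiplier must be >= 1")

    @property
    def error_free(self) -> bool:
        return self.substitution == self.insertion == self.deletion == 0.0


ERROR_FREE = ErrorModel(0.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class CassetteSpec:
    """Marker cassette top strand 5'->3' including both junction bases.

    The sequence starts with the first base after the upstream dT
    overhang and ends with the downstream overhang T itself; the first
    and last ``anchor_len`` bases serve as cassette-end anchors for the
    caller.
    """

    seq: str
    anchor_len: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise ValueError(f"cassette contains non-ACGT characters: {sorted(bad)}")
        if len(self.seq) <= 2 * self.anchor_len:
            raise ValueError("cassette must be longer than twice the anchor length")

    @property
    def anchor5(self) -> str:
        return self.seq[: self.anchor_len]

    @property
    def anchor3(self) -> str:
        return self.seq[-self.anchor_len :]


# ---------------------------------------------------------------------------
# nick placement


def enzyme_nicks(enzyme: EnzymeModel, ref: CircularRef) -> list[NickSet]:
    """One NickSet per recognition-site match (both strand orientations).

    For a '+' match starting at bond ``s`` the nicks fall at
    ``s + top_cut_offset`` / ``s + bottom_cut_offset``; '-' matches mirror
    the geometry about the site.  Palindromic sites yield one deduplicated
    NickSet per locus.  Zero matches return an empty list.
    """
    from .seqcore import iupac_find

    m = len(enzyme.recognition)
    out = []
    seen = set()
    for start, strand in iupac_find(enzyme.recognition, ref, both_strands=True):
        if strand == "+":
            top = (start + enzyme.top_cut_offset) % ref.L
            bottom = (start + enzyme.bottom_cut_offset) % ref.L
        else:
            top = (start + m - enzyme.bottom_cut_offset) % ref.L
            bottom = (start + m - enzyme.top_cut_offset) % ref.L
        key = (top, bottom)
        if key in seen:
            continue
        seen.add(key)
        out.append(NickSet({top}, {bottom}))
    return out


def _locus_arc(nicks: NickSet, L: int):
    """Shortest circular arc (start_bond, span) containing every nick."""
    bonds = sorted(set(nicks.top) | set(nicks.bottom))
    if len(bonds) == 1:
        return bonds[0], 0
    gaps = [
        ((bonds[(i + 1) % len(bonds)] - bonds[i]) % L, i)
        for i in range(len(bonds))
    ]
    widest, idx = max(gaps)
    start = bonds[(idx + 1) % len(bonds)]
    return start, L - widest


def resolve_repair(nicks: NickSet, L: int, window: int | None = None):
    """Nick pair surviving end repair: ``(reported_top, reported_bottom)``.

    End repair blunts both ends of the recovered fragment, so the
    reported top-strand nick is the one closest to the top strand's 3'
    end within the locus (maximal in local 5'->3' order) and the reported
    bottom-strand nick the one closest to the bottom strand's 3' end
    (minimal in the same frame).  Nicks spread over an arc wider than
    ``window`` (default ``L // 2 - 1``) raise :class:`UnlinkedNicksError`.
    """
    if window is None:
        window = L // 2 - 1
    start, span = _locus_arc(nicks, L)
    if span > window:
        raise UnlinkedNicksError(
            f"nicks span {span} bonds, beyond linkage window {window}"
        )
    local = lambda b: (b - start) % L
    reported_top = max(nicks.top, key=local)
    reported_bottom = min(nicks.bottom, key=local)
    return reported_top, reported_bottom


def classify_overhang(top: int, bottom: int, L: int, window: int | None = None):
    """(type, length) of the duplex end geometry for a linked nick pair."""
    if window is None:
        window = L // 2 - 1
    d = circ_delta(top, bottom, L)
    if abs(d) > window:
        return "distant", abs(d)
    if d > 0:
        return "5p", d
    if d < 0:
        return "3p", -d
    return "blunt", 0


def build_plasmid(
    ref: CircularRef,
    nicks: NickSet,
    cassette: CassetteSpec,
    orientation: str = "+",
    window: int | None = None,
    min_insert: int = 100,
):
    """End-repair, dA-tail and TA-ligate one cleavage event.

    Returns ``(plasmid_seq, truth)`` where ``plasmid_seq`` is the ligated
    circle written with the cassette on the top strand:
    ``[repaired insert][A][cassette]`` — the cassette's terminal T forms
    the second TA junction (its partner dA sits on the bottom strand).
    ``orientation`` records which way the cassette ligated relative to
    the insert; '-' writes the insert reverse-complemented, which is the
    same molecule read on its other strand.

    ``truth`` records the nick pair that sequence-level repair preserves
    (see :func:`resolve_repair`); internal fragments between multiple
    nicks are lost during cloning and do not appear in the product.
    """
    if orientation not in ("+", "-"):
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    top, bottom = resolve_repair(nicks, ref.L, window)
    d = circ_delta(top, bottom, ref.L)
    insert_len = ref.L + d
    if insert_len < min_insert:
        raise RejectedEventError(
            f"break removes {ref.L - insert_len} bp, insert {insert_len} < {min_insert}"
        )
    doubled = ref.seq + ref.seq
    insert = doubled[top : top + insert_len]
    if orientation == "-":
        insert = revcomp(insert)
    plasmid = insert + "A" + cassette.seq
    otype, olen = classify_overhang(top, bottom, ref.L, window)
    truth = {
        "reported_top": top,
        "reported_bottom": bottom,
        "overhang_type": otype,
        "overhang_len": olen,
        "orientation": orientation,
        "insert_len": insert_len,
    }
    return plasmid, truth


# ---------------------------------------------------------------------------
# event sampling


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def collision_point(model: CollisionModel, rng) -> int:
    """Sample the collision position ``n`` in ``[0, d]``."""
    rng = _as_rng(rng)
    if model.dissociation == 0.0:
        return int(rng.binomial(model.d, 0.5))
    # explicit walker simulation with per-step dissociation/re-initiation
    a, b = 0, model.d
    while a < b:
        mover_a = rng.random() < 0.5
        if rng.random() < model.dissociation:
            if mover_a:
                a = 0
            else:
                b = model.d
            continue
        if mover_a:
            a += 1
        else:
            b -= 1
    return a


def sample_events(model, n_events: int, rng, L: int | None = None) -> list[NickSet]:
    """Draw ``n_events`` NickSets from an EventDistribution or CollisionModel.

    ``L`` (substrate length) wraps collision-model nick positions onto the
    circle; omit it for abstract sampling on the integer line.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = _as_rng(rng)
    wrap = (lambda x: x % L) if L else (lambda x: x)
    out: list[NickSet] = []
    if isinstance(model, CollisionModel):
        for _ in range(n_events):
            c = model.origin + collision_point(model, rng)
            if model.mode == "symmetric":
                s1 = s2 = model.min_half_spacing + int(rng.geometric(model.spread_p)) - 1
            else:
                s1 = model.min_half_spacing + int(rng.geometric(model.spread_p)) - 1
                s2 = model.min_half_spacing + int(rng.geometric(model.spread_p)) - 1
            # outward nicking leaves the bottom nick upstream of the top nick:
            # d = bottom - top = -(s1 + s2) <= 0, a 3' overhang
            out.append(NickSet({wrap(c + s1)}, {wrap(c - s2)}))
        return out
    if not isinstance(model, EventDistribution):
        raise TypeError(f"unsupported event model {type(model).__name__}")
    if model.joint_pairs is not None:
        pairs = list(model.joint_pairs.keys())
        probs = np.array([model.joint_pairs[p] for p in pairs], dtype=float)
        idx = rng.choice(len(pairs), size=n_events, p=probs / probs.sum())
        return [NickSet({pairs[i][0]}, {pairs[i][1]}) for i in idx]
    tops = list(model.top_dist.keys())
    tprobs = np.array([model.top_dist[t] for t in tops], dtype=float)
    t_idx = rng.choice(len(tops), size=n_events, p=tprobs / tprobs.sum())
    conditional = isinstance(next(iter(model.bottom_dist.values())), dict)
    if not conditional:
        bots = list(model.bottom_dist.keys())
        bprobs = np.array([model.bottom_dist[b] for b in bots], dtype=float)
        b_idx = rng.choice(len(bots), size=n_events, p=bprobs / bprobs.sum())
        return [
            NickSet({tops[i]}, {bots[j]}) for i, j in zip(t_idx, b_idx)
        ]
    out = []
    for i in t_idx:
        tbl = model.bottom_dist[tops[i]]
        bots = list(tbl.keys())
        bprobs = np.array([tbl[b] for b in bots], dtype=float)
        j = rng.choice(len(bots), p=bprobs / bprobs.sum())
        out.append(NickSet({tops[i]}, {bots[j]}))
    return out


# ---------------------------------------------------------------------------
# read emission

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def apply_errors(seq: str, err: ErrorModel, rng) -> str:
    """Inject i.i.d. substitutions/indels; deletions up-weighted in runs >= 3."""
    if err.error_free:
        return seq
    rng = _as_rng(rng)
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = a.size
    # per-position homopolymer run length
    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(a[1:], a[:-1], out=change[1:])
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    in_run = run_len[run_id] >= 3
    p_del = np.where(
        in_run,
        min(err.deletion * err.homopolymer_deletion_multiplier, 0.95),
        err.deletion,
    )
    del_mask = rng.random(n) < p_del
    sub_mask = (~del_mask) & (rng.random(n) < err.substitution)
    sub_idx = np.nonzero(sub_mask)[0]
    if sub_idx.size:
        cur = _BASE_INDEX[a[sub_idx]]
        a[sub_idx] = _BASES[(cur + rng.integers(1, 4, size=sub_idx.size)) % 4]
    a = np.delete(a, np.nonzero(del_mask)[0])
    ins_mask = rng.random(a.size + 1) < err.insertion
    ins_pos = np.nonzero(ins_mask)[0]
    if ins_pos.size:
        a = np.insert(a, ins_pos, _BASES[rng.integers(0, 4, size=ins_pos.size)])
    return a.tobytes().decode("ascii")


def emit_concatemer(
    plasmid: str,
    repeats: int,
    rotation: int,
    strand: str,
    err: ErrorModel,
    rng,
    quality_q: int = 20,
):
    """Rolling-circle concatemer read: ``repeats`` tandem copies plus errors.

    The template circle is rotated to ``rotation`` before copying; '-'
    strand reads are the reverse complement of the whole concatemer.
    A flat synthetic Phred quality ``quality_q`` is attached.
    Returns ``(seq, qual)``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    rotation %= len(plasmid)
    monomer = plasmid[rotation:] + plasmid[:rotation]
    concat = monomer * repeats
    if strand == "-":
        concat = revcomp(concat)
    seq = apply_errors(concat, err, rng)
    return seq, chr(33 + quality_q) * len(seq)


def simulate_library(
    ref: CircularRef,
    cassette: CassetteSpec,
    events: list[NickSet],
    err: ErrorModel,
    rng,
    repeats_choices=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12),
    quality_q: int = 20,
    window: int | None = None,
    id_prefix: str = "ev",
):
    """Turn a list of cleavage events into concatemer reads plus a truth table.

    Per event, the repeat number, rotation, read strand and cassette
    ligation orientation are drawn from ``rng``.  Returns
    ``(reads, truth)`` where ``reads`` is a list of ``(id, seq, qual)``
    and ``truth`` a DataFrame with one row per emitted read.
    """
    rng = _as_rng(rng)
    reads = []
    rows = []
    repeats_choices = list(repeats_choices)
    for i, nicks in enumerate(events):
        orientation = "+" if rng.random() < 0.5 else "-"
        try:
            plasmid, truth = build_plasmid(
                ref, nicks, cassette, orientation=orientation, window=window
            )
        except (UnlinkedNicksError, RejectedEventError):
            continue
        repeats = int(repeats_choices[rng.integers(0, len(repeats_choices))])
        rotation = int(rng.integers(0, len(plasmid)))
        strand = "+" if rng.random() < 0.5 else "-"
        read_id = f"{id_prefix}{i:05d}"
        seq, qual = emit_concatemer(
            plasmid, repeats, rotation, strand, err, rng, quality_q
        )
        reads.append((read_id, seq, qual))
        rows.append(
            {
                "read_id": read_id,
                **truth,
                "repeats": repeats,
                "rotation": rotation,
                "strand": strand,
            }
        )
    truth_df = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "reported_top",
            "reported_bottom",
            "overhang_type",
            "overhang_len",
            "orientation",
            "insert_len",
            "repeats",
            "rotation",
            "strand",
        ],
    )
    return reads, truth_df
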