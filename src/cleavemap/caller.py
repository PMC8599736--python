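"""Cleavage-site calling: triangulate linked nick pairs from consensus reads.

Each consensus read of a cleavage-event library is the circular ligation
product ``[repaired insert][A][marker cassette]``.  The caller

1. finds both cassette ends in the consensus (treated as circular, both
   strands) by exact anchor matching and canonicalises the read so the
   cassette is forward and the insert contiguous (:func:`locate_cassette`);
2. extracts the sequences flanking the cassette, discarding the
   non-templated dA at the upstream junction (:func:`extract_flanks`);
3. aligns both flanks to the circular reference — exact search first,
   then a scored local alignment with an ambiguity margin
   (:func:`align_flank`);
4. orients the insert against the reference with a "mid-flag" sequence
   taken midway between the cassette ends (:func:`resolve_orientation`);
5. scores cleavage at the 3' end of the 5'-flank alignment on the
   opposite strand, and at the 5' end of the 3'-flank alignment on the
   same strand, yielding the linked (top, bottom) nick pair and its
   overhang class (:func:`triangulate`).

Reads that cannot be called are classified into an error taxonomy
(missing/multiple anchors, unalignable or ambiguous flanks, mid-flag
failure, distant nicks) summarised per library by :func:`call_library`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusRead
from .seqcore import CircularRef, circ_delta, revcomp
from .simulate import CassetteSpec, classify_overhang

__all__ = [
    "CallerParams",
    "CleavageCall",
    "CallError",
    "STATUS_CODES",
    "locate_cassette",
    "extract_flanks",
    "align_flank",
    "resolve_orientation",
    "triangulate",
    "call_read",
    "call_library",
    "calls_to_frame",
]

OK = "OK"
MISSING_5P_ANCHOR = "MISSING_5P_ANCHOR"
MISSING_3P_ANCHOR = "MISSING_3P_ANCHOR"
MULTIPLE_CASSETTES = "MULTIPLE_CASSETTES"
FLANK_NO_HIT = "FLANK_NO_HIT"
FLANK_AMBIGUOUS = "FLANK_AMBIGUOUS"
MIDFLAG_FAIL = "MIDFLAG_FAIL"
DISTANT_NICKS = "DISTANT_NICKS"

STATUS_CODES = (
    MISSING_5P_ANCHOR,
    MISSING_3P_ANCHOR,
    MULTIPLE_CASSETTES,
    FLANK_NO_HIT,
    FLANK_AMBIGUOUS,
    MIDFLAG_FAIL,
    DISTANT_NICKS,
)


class CallError(Exception):
    """A per-read calling failure carrying its error-taxonomy code."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


@dataclass
class CallerParams:
    """Tunable parameters of the caller.

    Anchors are exact by default (``anchor_max_mismatch = 0``); the
    mismatch-tolerant mode exists for degraded data but is off by
    default.  ``junction_trim`` removes the non-templated dA between
    insert and cassette before flank extraction (set 0 to keep it and
    absorb it through alignment scoring instead).  Stage-2 flank
    alignment scores +1 match / -1 mismatch / -2 gap; a hit needs
    ``min_flank_score`` (default ``flank_len - 4``) and is ambiguous when
    a second locus scores within ``ambiguity_margin`` of the best.
    ``max_nick_separation`` (default ``L//2 - 1``) bounds the linked
    nick spacing before a call is classed distant.
    """

    anchor_len: int = 20
    flank_len: int = 20
    junction_trim: int = 1
    midflag_len: int = 20
    min_flank_score: int | None = None
    ambiguity_margin: int = 2
    max_nick_separation: int | None = None
    anchor_max_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.anchor_len < 8 or self.flank_len < 8:
            raise ValueError("anchor_len and flank_len must be >= 8")
        if self.junction_trim not in (0, 1):
            raise ValueError("junction_trim must be 0 or 1")

    @property
    def flank_min_score(self) -> int:
        return (
            self.min_flank_score
            if self.min_flank_score is not None
            else self.flank_len - 4
        )


@dataclass
class CleavageCall:
    """One called (or failed) cleavage event."""

    read_id: str
    status: str
    top_nick: int | None = None
    bottom_nick: int | None = None
    overhang_type: str | None = None
    overhang_len: int | None = None
    orientation: str | None = None
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.status == OK:
            assert self.overhang_len is not None
            if self.overhang_type == "blunt":
                assert self.top_nick == self.bottom_nick


@dataclass(frozen=True)
class FlankHit:
    strand: str
    top_start: int  # top-frame coordinate of first aligned reference base
    top_end: int  # top-frame coordinate of last aligned reference base
    qstart: int
    qend: int
    score: float
    runner_up: float | None


# ---------------------------------------------------------------------------
# exact circular substring search


def _circ_occurrences(seq: str, sub: str, max_mm: int = 0) -> list[int]:
    """Start positions (mod len(seq)) of ``sub`` in circular ``seq``."""
    n, m = len(seq), len(sub)
    if m > n:
        return []
    doubled = seq + seq[: m - 1]
    if max_mm == 0:
        out = []
        i = doubled.find(sub)
        while i != -1:
            if i < n:
                out.append(i)
            i = doubled.find(sub, i + 1)
        return out
    arr = np.frombuffer(doubled.encode("ascii"), dtype=np.uint8)
    probe = np.frombuffer(sub.encode("ascii"), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, m)
    mm = (win != probe).sum(axis=1)
    return [int(i) for i in np.nonzero(mm <= max_mm)[0] if i < n]


# ---------------------------------------------------------------------------
# cassette location / canonical form


def locate_cassette(consensus: str, cassette: CassetteSpec, p: CallerParams):
    """Find the cassette in a circular consensus and canonicalise the read.

    Returns ``(canonical, span_len, input_strand)``: ``canonical`` is the
    consensus rotated (and reverse-complemented if needed) so it reads
    ``[insert][A][cassette]`` with the cassette forward at the end;
    ``span_len`` is the observed cassette length (5' anchor start to 3'
    anchor end) and ``input_strand`` which strand of the input carried
    the forward cassette.

    Raises :class:`CallError` with ``MISSING_5P_ANCHOR`` /
    ``MISSING_3P_ANCHOR`` when an anchor is absent (only reads containing
    both cassette ends are retained) or ``MULTIPLE_CASSETTES`` when an
    anchor occurs more than once or the anchors disagree on strand.
    """
    a5 = cassette.anchor5[: p.anchor_len]
    a3 = cassette.anchor3[-p.anchor_len :]
    mm = p.anchor_max_mismatch
    occ5_f = _circ_occurrences(consensus, a5, mm)
    occ5_r = _circ_occurrences(consensus, revcomp(a5), mm)
    occ3_f = _circ_occurrences(consensus, a3, mm)
    occ3_r = _circ_occurrences(consensus, revcomp(a3), mm)
    n5 = len(occ5_f) + len(occ5_r)
    n3 = len(occ3_f) + len(occ3_r)
    if n5 == 0:
        raise CallError(MISSING_5P_ANCHOR, "5' cassette anchor not found")
    if n3 == 0:
        raise CallError(MISSING_3P_ANCHOR, "3' cassette anchor not found")
    if n5 > 1 or n3 > 1:
        raise CallError(MULTIPLE_CASSETTES, "anchor occurs more than once")
    if bool(occ5_f) != bool(occ3_f):
        raise CallError(MULTIPLE_CASSETTES, "cassette anchors on opposite strands")
    strand = "+" if occ5_f else "-"
    work = consensus if strand == "+" else revcomp(consensus)
    if strand == "-":
        occ5_f = _circ_occurrences(work, a5, mm)
        occ3_f = _circ_occurrences(work, a3, mm)
    n = len(work)
    a5_start = occ5_f[0]
    a3_end = (occ3_f[0] + p.anchor_len) % n
    span_len = (a3_end - a5_start) % n
    if span_len < 2 * p.anchor_len:
        raise CallError(MULTIPLE_CASSETTES, "inconsistent anchor geometry")
    canonical = work[a3_end:] + work[:a3_end]
    return canonical, span_len, strand


def extract_flanks(canonical: str, span_len: int, p: CallerParams):
    """Flanks adjacent to the cassette ends of a canonicalised consensus.

    ``flank5`` is the ``flank_len`` bases immediately 5' of the cassette
    after discarding ``junction_trim`` base(s) (the non-templated dA);
    ``flank3`` the ``flank_len`` bases immediately 3' of the cassette's
    terminal T, which belongs to the cassette.  Returns
    ``(flank5, flank3, overlapping)``; ``overlapping`` flags inserts too
    short for disjoint flanks.
    """
    n = len(canonical)
    insert = canonical[: n - span_len]
    if len(insert) < p.flank_len + p.junction_trim:
        raise CallError(
            FLANK_NO_HIT,
            f"insert of {len(insert)} bp shorter than flank_len + trim",
        )
    end = len(insert) - p.junction_trim
    flank5 = insert[end - p.flank_len : end]
    flank3 = insert[: p.flank_len]
    overlapping = len(insert) < 2 * p.flank_len + p.junction_trim
    return flank5, flank3, overlapping


# ---------------------------------------------------------------------------
# flank alignment (stage 1 exact, stage 2 scored local alignment)


def _sw_colmax(query: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Best Smith-Waterman score ending at each target position.

    Linear gap model (+1 match, -1 mismatch, -2 gap).  The horizontal
    (target-gap) recurrence is solved exactly with a decayed running
    maximum, making the scan O(m) vectorised passes over the target.
    """
    n = target.size
    idx2 = 2.0 * np.arange(n)
    prev = np.zeros(n + 1)
    colmax = np.zeros(n)
    for qi in range(query.size):
        s = np.where(target == query[qi], 1.0, -1.0)
        h0 = np.maximum(0.0, np.maximum(prev[:-1] + s, prev[1:] - 2.0))
        cur = np.maximum(h0, np.maximum.accumulate(h0 + idx2) - idx2)
        np.maximum(colmax, cur, out=colmax)
        prev[1:] = cur
    return colmax


def _sw_traceback(query: str, window: str):
    """Full local DP over a small window; returns the best cell alignment.

    Returns ``(score, qstart, qend, tstart, tend)`` with the target
    coordinates relative to the window and the best cell chosen as the
    highest-scoring, rightmost target column.
    """
    m, w = len(query), len(window)
    H = np.zeros((m + 1, w + 1))
    for i in range(1, m + 1):
        qc = query[i - 1]
        for j in range(1, w + 1):
            sc = 1.0 if window[j - 1] == qc else -1.0
            H[i, j] = max(0.0, H[i - 1, j - 1] + sc, H[i - 1, j] - 2.0, H[i, j - 1] - 2.0)
    best = H.max()
    cells = np.argwhere(H == best)
    # prefer the rightmost target column, then the deepest query row
    i, j = max(cells, key=lambda c: (c[1], c[0]))
    qend, tend = i - 1, j - 1
    while i > 0 and j > 0 and H[i, j] > 0:
        sc = 1.0 if window[j - 1] == query[i - 1] else -1.0
        if H[i, j] == H[i - 1, j - 1] + sc:
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] - 2.0:
            i -= 1
        else:
            j -= 1
    return float(best), i, qend, j, tend


def _bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def align_flank(flank: str, ref: CircularRef, p: CallerParams) -> FlankHit:
    """Best circular hit of a flank on either reference strand.

    Stage 1 searches both strands of the doubled reference for exact
    occurrences; a unique exact hit scores ``len(flank)``.  Stage 2 (only
    when no exact hit exists) runs the scored local alignment scan; the
    hit is accepted iff its score reaches ``flank_min_score`` and is
    ambiguous iff a second locus (different position or strand) scores
    within ``ambiguity_margin`` of the best.
    """
    m = len(flank)
    if m < 8:
        raise CallError(FLANK_NO_HIT, "flank shorter than 8 bases")
    L = ref.L
    exact_f = _circ_occurrences(ref.seq, flank)
    exact_r = _circ_occurrences(ref.seq, revcomp(flank))
    loci = [(s, "+") for s in exact_f] + [(s, "-") for s in exact_r]
    if len(loci) > 1:
        raise CallError(FLANK_AMBIGUOUS, f"{len(loci)} exact loci")
    if len(loci) == 1:
        s, strand = loci[0]
        e = (s + m - 1) % L
        return FlankHit(strand, s, e, 0, m - 1, float(m), None)
    # stage 2: scored scan over the doubled reference, both strands
    doubled_f = ref.seq + ref.seq
    doubled_r = revcomp(ref.seq) * 2
    q = _bytes(flank)
    col_f = _sw_colmax(q, _bytes(doubled_f))
    col_r = _sw_colmax(q, _bytes(doubled_r))
    best_f, best_r = col_f.max(), col_r.max()
    strand = "+" if best_f >= best_r else "-"
    cols, target = (col_f, doubled_f) if strand == "+" else (col_r, doubled_r)
    best = float(cols.max())
    if best < p.flank_min_score:
        raise CallError(FLANK_NO_HIT, f"best local score {best} < {p.flank_min_score}")
    jstar = int(cols.argmax())
    # runner-up: same strand outside the locus (both doubled copies), plus
    # the best of the other strand anywhere
    offs = (np.arange(cols.size) - jstar) % L
    away = (offs > m + 2) & (offs < L - (m + 2))
    runner_same = float(cols[away].max()) if away.any() else 0.0
    runner_other = float((col_r if strand == "+" else col_f).max())
    runner_up = max(runner_same, runner_other)
    if runner_up >= best - p.ambiguity_margin:
        raise CallError(
            FLANK_AMBIGUOUS, f"runner-up {runner_up} within margin of best {best}"
        )
    w0 = max(0, jstar - (2 * m + 4))
    score, qs, qe, ts, te = _sw_traceback(flank, target[w0 : jstar + 1])
    tstart, tend = w0 + ts, w0 + te
    if strand == "+":
        top_start, top_end = tstart % L, tend % L
    else:
        top_start, top_end = (L - 1 - tend) % L, (L - 1 - tstart) % L
    return FlankHit(strand, top_start, top_end, qs, qe, score, runner_up)


# ---------------------------------------------------------------------------
# orientation and triangulation


def resolve_orientation(
    canonical: str, span_len: int, ref: CircularRef, p: CallerParams
) -> str:
    """Strand of the insert on the reference, fixed by the mid-flag.

    The mid-flag is ``midflag_len`` bases taken at the midpoint of the
    insert arc; its unique hit on the reference decides whether the
    canonical insert reads along the reference top ('+') or bottom ('-')
    strand, which in turn decides which flank reports which strand nick.
    """
    n = len(canonical)
    insert = canonical[: n - span_len]
    usable = insert[: max(0, len(insert) - p.junction_trim)]
    if len(usable) < p.midflag_len:
        raise CallError(MIDFLAG_FAIL, "insert too short for a mid-flag")
    mid = len(usable) // 2
    start = min(max(0, mid - p.midflag_len // 2), len(usable) - p.midflag_len)
    midflag = usable[start : start + p.midflag_len]
    try:
        hit = align_flank(midflag, ref, p)
    except CallError as err:
        raise CallError(MIDFLAG_FAIL, f"mid-flag {err.code}") from err
    return hit.strand


def triangulate(
    hit5: FlankHit,
    hit3: FlankHit,
    orientation: str,
    ref: CircularRef,
    p: CallerParams,
    read_id: str = "",
    repeats: int = 1,
) -> CleavageCall:
    """Linked nick pair from the two flank hits.

    For the 5' flank, cleavage is scored at the bond 3' of its last
    aligned base on the opposite strand; for the 3' flank, at the bond of
    its first aligned base on the same strand.  In reference top-strand
    bond coordinates this gives, for a forward-oriented insert, the
    bottom nick from the 5' flank and the top nick from the 3' flank;
    a reverse-oriented insert swaps the roles.  Flank strands must agree
    with the mid-flag orientation.
    """
    if hit5.strand != orientation or hit3.strand != orientation:
        raise CallError(MIDFLAG_FAIL, "flank strands inconsistent with mid-flag")
    L = ref.L
    m5_ext = p.flank_len - 1 - hit5.qend  # junction-side bases clipped by DP
    m3_ext = hit3.qstart
    if orientation == "+":
        bottom = (hit5.top_end + 1 + m5_ext) % L
        top = (hit3.top_start - m3_ext) % L
    else:
        top = (hit5.top_start - m5_ext) % L
        bottom = (hit3.top_end + 1 + m3_ext) % L
    window = p.max_nick_separation if p.max_nick_separation is not None else L // 2 - 1
    otype, olen = classify_overhang(top, bottom, L, window)
    status = OK if otype != "distant" else DISTANT_NICKS
    return CleavageCall(
        read_id=read_id,
        status=status,
        top_nick=top,
        bottom_nick=bottom,
        overhang_type=otype,
        overhang_len=olen,
        orientation=orientation,
        repeats=repeats,
    )


def call_read(
    cread: ConsensusRead, ref: CircularRef, cassette: CassetteSpec, p: CallerParams
) -> CleavageCall:
    """Run the full calling cascade on one consensus read."""
    try:
        canonical, span_len, _ = locate_cassette(cread.seq, cassette, p)
        flank5, flank3, _ = extract_flanks(canonical, span_len, p)
        orientation = resolve_orientation(canonical, span_len, ref, p)
        hit5 = align_flank(flank5, ref, p)
        hit3 = align_flank(flank3, ref, p)
        return triangulate(
            hit5, hit3, orientation, ref, p, read_id=cread.id, repeats=cread.repeats
        )
    except CallError as err:
        return CleavageCall(read_id=cread.id, status=err.code, repeats=cread.repeats)


def call_library(
    consensus_reads,
    ref: CircularRef,
    cassette: CassetteSpec,
    p: CallerParams | None = None,
    min_repeats: int = 1,
):
    """Call every consensus read with ``repeats >= min_repeats``.

    Returns ``(calls, summary)``: calls in input order (one per attempted
    read) and a Counter over status codes whose total equals the number
    of attempted reads.
    """
    p = p or CallerParams()
    calls = []
    summary: Counter = Counter()
    for cread in consensus_reads:
        if cread.repeats < min_repeats:
            continue
        call = call_read(cread, ref, cassette, p)
        calls.append(call)
        summary[call.status] += 1
    return calls, summary


def calls_to_frame(calls) -> pd.DataFrame:
    """Calls as a tidy table with a stable column order."""
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "status": c.status,
                "top_nick": c.top_nick,
                "bottom_nick": c.bottom_nick,
                "overhang_type": c.overhang_type,
                "overhang_len": c.overhang_len,
                "orientation": c.orientation,
                "repeats": c.repeats,
            }
            for c in calls
        ],
        columns=[
            "read_id",
            "status",
            "top_nick",
            "bottom_nick",
            "overhang_type",
            "overhang_len",
            "orientation",
            "repeats",
        ],
    )
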