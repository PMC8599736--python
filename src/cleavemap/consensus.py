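"""Concatemer consensus: split tandem-repeat reads and vote per column.

A rolling-circle read is R tandem copies of one circular template.  The
repeat period is found from approximate recurrences of a short probe,
the read is split into subreads, and a per-column majority vote against
the first full subread yields the consensus.  This is a deliberately
simple, splint-free stand-in for graph-based concatemer consensus tools:
majority voting is adequate at the error rates the simulator produces
and keeps the repeat count ("repeats") semantics — the number of full
subreads backing each consensus — which downstream accuracy filtering
relies on.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from .io import FastqRead
from .seqcore import CircularRef, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusRead",
    "FilterParams",
    "prefilter",
    "mean_quality",
    "estimate_period",
    "build_consensus",
    "identity_vs_reference",
]

_CIGAR_RX = re.compile(r"(\d+)([=XIDM])")

_BASE_INDEX = np.full(256, 4, dtype=np.int64)  # non-ACGT votes as gap
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class ConsensusRead:
    """One consensus sequence with its subread count and provenance."""

    id: str
    seq: str
    repeats: int
    mean_q: float
    source_len: int

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if len(self.seq) > self.source_len:
            raise ValueError("consensus cannot be longer than its source read")


@dataclass
class FilterParams:
    """Raw-read retention thresholds (both strict inequalities)."""

    min_q: float = 11.0
    min_len: int = 2000
    min_repeats: int = 1

    def __post_init__(self) -> None:
        if self.min_q < 0 or self.min_len < 0 or self.min_repeats < 0:
            raise ValueError("filter thresholds must be non-negative")


def mean_quality(qual: str) -> float:
    """Read-level mean Phred quality via probability-domain averaging.

    Phred scores are converted to error probabilities, averaged, and
    converted back; this is monotone and dominated by the worst bases,
    matching how basecallers summarise read quality.
    """
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - 33.0
    p_err = np.power(10.0, -q / 10.0)
    return float(-10.0 * np.log10(p_err.mean()))


def prefilter(reads, params: FilterParams):
    """Keep reads with mean Q > ``min_q`` AND length > ``min_len``.

    Returns ``(kept, stats)`` with drop counts by reason (length checked
    first).
    """
    kept = []
    stats = {"input": 0, "kept": 0, "dropped_len": 0, "dropped_q": 0}
    for read in reads:
        stats["input"] += 1
        if len(read.seq) <= params.min_len:
            stats["dropped_len"] += 1
            continue
        if mean_quality(read.qual) <= params.min_q:
            stats["dropped_q"] += 1
            continue
        stats["kept"] += 1
        kept.append(read)
    return kept, stats


# ---------------------------------------------------------------------------
# period detection


def _recurrences(arr: np.ndarray, probe: np.ndarray, max_mm: int) -> list[int]:
    """Start positions where the probe matches with <= max_mm mismatches."""
    m = probe.size
    if arr.size < m:
        return []
    win = np.lib.stride_tricks.sliding_window_view(arr, m)
    mm = (win != probe).sum(axis=1)
    pos = np.nonzero(mm <= max_mm)[0]
    keep: list[int] = []
    last = -m
    for p in pos.tolist():  # collapse runs of overlapping near-matches
        if p - last >= m:
            keep.append(p)
            last = p
    return keep


def _best_recurrences(seq: str, probe_len: int = 24, max_mm: int = 2):
    """Probe positions for the probe with the most approximate recurrences."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if arr.size < 2 * probe_len:
        return []
    offsets = [o for o in (100, 0, 37, 74, 148) if o + probe_len <= arr.size]
    best: list[int] = []
    for off in offsets:
        probe = arr[off : off + probe_len]
        if np.all(probe == probe[0]):
            continue  # homopolymer probes recur spuriously
        pos = _recurrences(arr, probe, max_mm)
        if len(pos) > len(best):
            best = pos
    return best


def estimate_period(read: FastqRead | str, probe_len: int = 24) -> int | None:
    """Repeat period as the median spacing between probe recurrences.

    Returns ``None`` when no probe recurs at least twice (non-repetitive
    read, or a read holding a single template copy).
    """
    seq = read if isinstance(read, str) else read.seq
    pos = _best_recurrences(seq, probe_len)
    if len(pos) < 2:
        return None
    diffs = np.diff(pos)
    # a probe corrupted in one copy merges consecutive spacings into a
    # multiple of the period; normalise by the inferred copy multiplicity
    base = diffs.min()
    ks = np.maximum(1, np.round(diffs / base))
    return int(round(diffs.sum() / ks.sum()))


# ---------------------------------------------------------------------------
# consensus construction


def _run_start(anchor: str, ai: int, base: str) -> int:
    """Leftmost column of the homopolymer run of ``base`` ending at ``ai``."""
    while ai > 0 and anchor[ai - 1] == base:
        ai -= 1
    return ai


def _vote_segment(seg: str, anchor: str, votes: np.ndarray, insertions: dict) -> None:
    res = edlib.align(seg, anchor, mode="NW", task="path")
    ai = qi = 0
    seg_b = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
    for count, op in _CIGAR_RX.findall(res["cigar"]):
        k = int(count)
        if op in ("=", "X", "M"):
            rows = np.arange(ai, ai + k)
            np.add.at(votes, (rows, _BASE_INDEX[seg_b[qi : qi + k]]), 1)
            ai += k
            qi += k
        elif op == "D":  # anchor base absent from this subread: vote gap
            votes[ai : ai + k, 4] += 1
            ai += k
        else:  # 'I': subread-only bases, candidate insertion before column ai.
            # A single-base insertion belonging to a homopolymer run can be
            # attached at either end of the run by the aligner; re-key it to
            # the run start so votes from different subreads pool (inserting
            # a base anywhere within a run of itself is the same sequence).
            piece = seg[qi : qi + k]
            j = ai
            if len(set(piece)) == 1:
                j = _run_start(anchor, ai, piece[0])
            insertions.setdefault(j, []).append(piece)
            qi += k


def build_consensus(read: FastqRead, period: int | None) -> ConsensusRead | None:
    """Majority-vote consensus of the subreads of one concatemer read.

    Subreads are the segments between consecutive probe recurrences, all
    globally aligned to the first full subread (the anchor).  Ties are
    resolved in favour of the anchor's base; a column is emitted only
    when gaps do not win it, and an insertion relative to the anchor is
    emitted when a strict majority of subreads carry one.  The terminal
    partial segments (before the first and after the last recurrence)
    wrap around the circle and are voted as one additional subread; it
    counts towards ``repeats`` only when it spans a full period.

    A read with no detectable period is passed through unchanged as a
    single-copy consensus (``repeats=1``).  Returns ``None`` when the
    read holds less than one full repeat.
    """
    mq = mean_quality(read.qual)
    if period is None:
        return ConsensusRead(read.id, read.seq, 1, mq, len(read.seq))
    pos = _best_recurrences(read.seq)
    if len(pos) < 2:
        return ConsensusRead(read.id, read.seq, 1, mq, len(read.seq))
    # a probe corrupted in one copy merges two periods into one segment;
    # split over-long gaps evenly so every segment spans ~one period
    refined = [pos[0]]
    for a, b in zip(pos[:-1], pos[1:]):
        k = max(1, round((b - a) / period))
        refined.extend(a + round(j * (b - a) / k) for j in range(1, k + 1))
    pos = refined
    segments = [read.seq[a:b] for a, b in zip(pos[:-1], pos[1:])]
    wrap = read.seq[pos[-1] :] + read.seq[: pos[0]]
    lo, hi = 0.8 * period, 1.2 * period
    wrap_parts = [wrap]
    if len(wrap) > hi:  # terminal partials straddle a missed boundary
        k = max(1, round(len(wrap) / period))
        cuts = [round(j * len(wrap) / k) for j in range(k + 1)]
        wrap_parts = [wrap[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
    full = [s for s in segments if lo <= len(s) <= hi]
    extras = [s for s in segments if not lo <= len(s) <= hi]
    full += [s for s in wrap_parts if lo <= len(s) <= hi]
    extras += [s for s in wrap_parts if not lo <= len(s) <= hi]
    if not full:
        logger.info("read %s: no full repeat at period %d, skipped", read.id, period)
        return None
    anchor = full[0]
    others = full[1:]
    partials = [s for s in extras if len(s) >= 30]
    repeats = len(full)
    if all(s == anchor for s in others) and not partials:
        return ConsensusRead(read.id, anchor, repeats, mq, len(read.seq))
    # pass 1: vote against the first full subread.  An error in the anchor
    # can split the compensating insertion votes over adjacent columns, so
    # a second pass re-votes every subread against the pass-1 draft, whose
    # residual error rate is far below any single subread's.
    draft = _vote_pass(anchor, others + partials, anchor_votes=True)
    seq = _vote_pass(draft, full + partials, anchor_votes=False)
    seq = seq[: len(read.seq)]
    return ConsensusRead(read.id, seq, repeats, mq, len(read.seq))


def _vote_pass(anchor: str, segments, anchor_votes: bool) -> str:
    """One round of per-column majority voting against an anchor sequence.

    Ties resolve to the anchor's base; an insertion relative to the
    anchor is emitted when a strict majority of voters carry one at the
    same column.
    """
    n_col = len(anchor)
    votes = np.zeros((n_col, 5), dtype=np.int32)
    anchor_idx = _BASE_INDEX[np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)]
    voters = 0
    if anchor_votes:
        votes[np.arange(n_col), anchor_idx] += 1
        voters += 1
    insertions: dict[int, list[str]] = {}
    for seg in segments:
        _vote_segment(seg, anchor, votes, insertions)
        voters += 1
    winner = votes.argmax(axis=1)
    maxv = votes.max(axis=1)
    tied = (votes == maxv[:, None]).sum(axis=1) > 1
    anchor_wins = tied & (votes[np.arange(n_col), anchor_idx] == maxv)
    winner[anchor_wins] = anchor_idx[anchor_wins]
    ins_at = {}
    for ai, pieces in insertions.items():
        if len(pieces) * 2 > voters:
            ins_at[ai] = Counter(pieces).most_common(1)[0][0]
    out: list[str] = []
    for col in range(n_col):
        if col in ins_at:
            out.append(ins_at[col])
        w = winner[col]
        if w < 4:
            out.append("ACGT"[w])
    if n_col in ins_at:
        out.append(ins_at[n_col])
    return "".join(out)


# ---------------------------------------------------------------------------
# accuracy vs reference


def _cigar_identity(cigar: str) -> float:
    matches = cols = 0
    for count, op in _CIGAR_RX.findall(cigar):
        k = int(count)
        cols += k
        if op == "=":
            matches += k
    return 100.0 * matches / cols if cols else 0.0


def identity_vs_reference(
    consensus, ref: CircularRef, seed_len: int = 20
) -> float:
    """Percent identity of a consensus against the best rotation/strand of a
    circular reference.

    The rotation is found by exact seeding with a ``seed_len``-mer from
    the consensus against the doubled reference (both strands), then an
    end-to-end global alignment is scored; identity is matches over
    alignment columns, in percent.  Returns 0.0 when no seed from either
    strand hits the reference (flagged in the log).
    """
    seq = consensus if isinstance(consensus, str) else consensus.seq
    if len(seq) < seed_len:
        return 0.0
    doubled = ref.seq + ref.seq
    for candidate in (seq, revcomp(seq)):
        rot = None
        for off in range(0, min(len(candidate) - seed_len, 400) + 1, 50):
            hit = doubled.find(candidate[off : off + seed_len])
            if hit >= 0:
                rot = (hit - off) % ref.L
                break
        if rot is not None:
            target = doubled[rot : rot + ref.L]
            res = edlib.align(candidate, target, mode="NW", task="path")
            return _cigar_identity(res["cigar"])
    logger.info("no seed hit against reference %s", ref.name)
    return 0.0
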