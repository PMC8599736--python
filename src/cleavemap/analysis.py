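"""Aggregate cleavage calls into the method's result artifacts.

Tables produced here are the canonical outputs: cleavage-site frequency
tables, strand-linkage matrices with per-strand marginals, dinucleotide
frequencies at the nick bonds, signed nick-spacing statistics and
tornado tables with event midpoints, the closed-form collision law for
two converging motors, and repeat-cutoff accuracy/retention sweeps.
Rendering them as plots is cosmetic and optional (`cleavemap.plots`).

Sign convention (see :mod:`cleavemap.seqcore`): spacing
``s = bottom_nick - top_nick`` taken with minimal circular magnitude;
``s > 0`` is the 5'-overhang class, ``s < 0`` the 3'-overhang class
(plotted unsigned with a class colour), ``s = 0`` blunt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import CircularRef, circ_delta

logger = logging.getLogger(__name__)

__all__ = [
    "SlpMatrix",
    "SpacingStats",
    "site_frequencies",
    "dinucleotide_frequencies",
    "slp",
    "spacing_stats",
    "tornado",
    "midpoint_histogram",
    "collision_pmf",
    "cutoff_sweep",
]

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


def _ok_calls(calls) -> list:
    return [c for c in calls if c.status == "OK"]


def site_frequencies(calls) -> pd.DataFrame:
    """Count and fraction per (top_nick, bottom_nick, overhang) signature.

    Fractions are over OK calls and sum to 1; descending count, ties
    broken by coordinates for a stable order.
    """
    ok = _ok_calls(calls)
    cols = ["top_nick", "bottom_nick", "overhang_type", "overhang_len"]
    if not ok:
        logger.warning("no OK calls: empty site-frequency table")
        return pd.DataFrame(columns=cols + ["count", "fraction"])
    df = pd.DataFrame(
        [(c.top_nick, c.bottom_nick, c.overhang_type, c.overhang_len) for c in ok],
        columns=cols,
    )
    out = (
        df.groupby(cols, as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["count"] + cols, ascending=[False, True, True, True, True])
        .reset_index(drop=True)
    )
    out["fraction"] = out["count"] / len(ok)
    return out


def _dinuc_top(ref: CircularRef, bond: int) -> str:
    return ref.seq[(bond - 1) % ref.L] + ref.seq[bond % ref.L]


def _dinuc_bottom(ref: CircularRef, bond: int) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return comp[ref.seq[bond % ref.L]] + comp[ref.seq[(bond - 1) % ref.L]]


def dinucleotide_frequencies(calls, ref: CircularRef) -> pd.DataFrame:
    """16-entry dinucleotide table per strand at the nicked bonds.

    For each OK call the two reference bases flanking the nicked bond are
    read 5'->3' on the nicked strand: the top table counts the top-strand
    dinucleotide at ``top_nick``, the bottom table the bottom-strand
    dinucleotide at ``bottom_nick``.  Each column sums to 1 (all zeros
    when there are no OK calls).
    """
    ok = _ok_calls(calls)
    top = pd.Series(0.0, index=DINUCLEOTIDES, name="top")
    bottom = pd.Series(0.0, index=DINUCLEOTIDES, name="bottom")
    for c in ok:
        top[_dinuc_top(ref, c.top_nick)] += 1
        bottom[_dinuc_bottom(ref, c.bottom_nick)] += 1
    if ok:
        top /= len(ok)
        bottom /= len(ok)
    out = pd.concat([top, bottom], axis=1)
    out.index.name = "dinucleotide"
    return out


@dataclass
class SlpMatrix:
    """Joint top/bottom nick-position frequencies with per-strand marginals."""

    matrix: pd.DataFrame  # index: top-strand bond, columns: bottom-strand bond
    top_marginal: pd.Series
    bottom_marginal: pd.Series
    overflow: int  # OK calls outside the requested window

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum()) + self.overflow


def slp(calls, window: tuple[int, int] | None = None) -> SlpMatrix:
    """Strand-linkage matrix over a position window.

    ``window`` is an inclusive ``(lo, hi)`` bond range shared by both
    axes; it defaults to the span of the OK calls.  Calls outside the
    window are counted in ``overflow``.  Marginals are exact row/column
    sums, the per-strand histograms of a strand-linkage plot.
    """
    ok = _ok_calls(calls)
    if window is None:
        if not ok:
            raise ValueError("cannot infer a window from zero OK calls")
        nicks = [c.top_nick for c in ok] + [c.bottom_nick for c in ok]
        window = (min(nicks), max(nicks))
    lo, hi = window
    positions = range(lo, hi + 1)
    mat = pd.DataFrame(0, index=positions, columns=positions, dtype=int)
    mat.index.name = "top_nick"
    mat.columns.name = "bottom_nick"
    overflow = 0
    for c in ok:
        if lo <= c.top_nick <= hi and lo <= c.bottom_nick <= hi:
            mat.loc[c.top_nick, c.bottom_nick] += 1
        else:
            overflow += 1
    return SlpMatrix(
        matrix=mat,
        top_marginal=mat.sum(axis=1),
        bottom_marginal=mat.sum(axis=0),
        overflow=overflow,
    )


@dataclass
class SpacingStats:
    """Signed nick-spacing distribution over OK calls."""

    spacings: np.ndarray
    median: float
    q1: float
    q3: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def spacing_stats(calls, L: int) -> SpacingStats:
    """Median and quartiles (linear interpolation) of signed spacings."""
    ok = _ok_calls(calls)
    s = np.array([circ_delta(c.top_nick, c.bottom_nick, L) for c in ok], dtype=float)
    if s.size == 0:
        return SpacingStats(s, float("nan"), float("nan"), float("nan"), 0)
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    return SpacingStats(s, float(med), float(q1), float(q3), int(s.size))


def tornado(calls, L: int) -> pd.DataFrame:
    """Events ranked by unsigned spacing, with circular midpoints.

    The midpoint of an event with odd spacing falls on a half-bond; it is
    reported at the floor with ``midpoint_half`` set, ready for 1-bp
    binning.  Ranking is by descending ``|spacing|`` with ties broken by
    read id (stable).
    """
    rows = []
    for c in _ok_calls(calls):
        s = circ_delta(c.top_nick, c.bottom_nick, L)
        mp2 = (2 * c.top_nick + s) % (2 * L)
        rows.append(
            {
                "read_id": c.read_id,
                "spacing": s,
                "abs_spacing": abs(s),
                "overhang_class": "5p" if s > 0 else ("3p" if s < 0 else "blunt"),
                "midpoint": mp2 // 2,
                "midpoint_half": bool(mp2 % 2),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "read_id", "spacing", "abs_spacing", "overhang_class",
            "midpoint", "midpoint_half",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["abs_spacing", "read_id"], ascending=[False, True]
        ).reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
    else:
        df.insert(0, "rank", pd.Series(dtype=int))
    return df


def midpoint_histogram(tornado_df: pd.DataFrame, L: int) -> pd.Series:
    """1-bp binned histogram of event midpoints over all bonds."""
    counts = np.zeros(L, dtype=int)
    for mp in tornado_df["midpoint"]:
        counts[int(mp) % L] += 1
    return pd.Series(counts, index=range(L), name="midpoint_count")


def collision_pmf(d: int) -> np.ndarray:
    """Collision law for two converging motors ``d`` steps apart.

    ``P(n) = d! / (n! (d-n)! 2^d)`` for the collision position
    ``n in [0, d]`` — a symmetric binomial evaluated in log space, so it
    stays normalised for separations of ~1000 steps.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    return stats.binom.pmf(np.arange(d + 1), d, 0.5)


def cutoff_sweep(calls, expected, cutoffs=(1, 2, 3, 5, 10)) -> pd.DataFrame:
    """Accuracy and data retention per repeat cutoff.

    ``expected`` is either a single ``(top, bottom)`` nick pair or a
    mapping ``read_id -> (top, bottom)``.  Per cutoff ``c``: accuracy is
    correct OK calls over OK calls among calls with ``repeats >= c``
    (NaN when the stratum has no OK calls), retention the fraction of all
    calls with ``repeats >= c``.
    """
    if isinstance(expected, dict):
        want = lambda c: expected.get(c.read_id)
    else:
        want = lambda c: tuple(expected)
    n_all = len(calls)
    rows = []
    for cutoff in cutoffs:
        stratum = [c for c in calls if c.repeats >= cutoff]
        ok = [c for c in stratum if c.status == "OK"]
        correct = sum(
            1 for c in ok if (c.top_nick, c.bottom_nick) == tuple(want(c) or ())
        )
        rows.append(
            {
                "cutoff": cutoff,
                "n_calls": len(stratum),
                "n_ok": len(ok),
                "n_correct": correct,
                "accuracy_pct": 100.0 * correct / len(ok) if ok else float("nan"),
                "retention_pct": 100.0 * len(stratum) / n_all if n_all else float("nan"),
            }
        )
    return pd.DataFrame(rows)
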