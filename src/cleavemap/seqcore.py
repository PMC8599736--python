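"""Nucleotide primitives and circular coordinate arithmetic.

Coordinate convention
---------------------
Positions on a circular reference of length ``L`` are *bond indices*:
integer ``b`` in ``[0, L)`` denotes the phosphodiester bond 5' of
top-strand base ``b``, i.e. the bond between bases ``b - 1 (mod L)`` and
``b``.  The same top-strand frame is used to index bottom-strand nicks.
A top-strand nick and a bottom-strand nick at the *same* bond constitute
a blunt double-strand break.

Overhang sign convention: for a linked nick pair the signed displacement
``d = circ_delta(top_nick, bottom_nick)`` classifies the end geometry:
``d > 0`` is a 5' overhang of length ``d`` (EcoRI-like), ``d < 0`` a
3' overhang of length ``|d|`` (PstI-like) and ``d == 0`` blunt.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "CircularRef",
    "revcomp",
    "iupac_find",
    "circ_substr",
    "circ_delta",
    "IUPAC_CODES",
]

#: IUPAC nucleotide codes -> set of matching unambiguous bases.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Involution: ``revcomp(revcomp(s)) == s`` for every valid input.
    Raises ``ValueError`` on characters outside the IUPAC alphabet
    (including ``U``; RNA is not supported).
    """
    s = seq.upper()
    bad = set(s) - set(_COMPLEMENT)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s.translate(_COMP_TABLE)[::-1]


@dataclass(frozen=True)
class CircularRef:
    """A circular double-stranded DNA reference (top strand stored 5'->3').

    ``seq`` is upper-cased on construction; only A/C/G/T are accepted
    (``U`` and ambiguity codes are rejected: the substrate is a fully
    determined plasmid sequence).
    """

    name: str
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError("empty reference sequence")
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"reference {self.name!r} contains non-ACGT characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    # convenience alias used throughout
    @property
    def L(self) -> int:  # noqa: N802 - domain notation
        return len(self.seq)

    @classmethod
    def from_fasta(cls, path) -> "CircularRef":
        """Load a single-record FASTA file as a circular reference.

        Multi-record files are rejected with an error naming the file.
        """
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected exactly one FASTA record in {path}, found {len(records)}"
            )
        rec = records[0]
        return cls(name=rec.id, seq=str(rec.seq))


def circ_substr(ref: CircularRef, start: int, n: int) -> str:
    """``n`` top-strand bases read 5'->3' from base ``start``, wrapping."""
    L = ref.L
    if not 0 <= start < L:
        raise ValueError(f"start {start} outside [0, {L})")
    if not 0 < n <= L:
        raise ValueError(f"length {n} outside (0, {L}]")
    doubled = ref.seq + ref.seq
    return doubled[start : start + n]


def circ_delta(a: int, b: int, L: int) -> int:
    """Signed displacement from bond ``a`` to bond ``b`` of minimal magnitude.

    Returns ``d`` with ``(a + d) % L == b % L`` and ``|d|`` minimal; an
    exact half-circle tie resolves to ``+L/2``.  Callers decide whether a
    displacement is within their window of interest.
    """
    d = (b - a) % L
    if d * 2 > L:
        d -= L
    return d


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC_CODES:
            raise ValueError(f"non-IUPAC character in pattern: {ch!r}")
        opts = IUPAC_CODES[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def iupac_find(pattern: str, ref: CircularRef, both_strands: bool = True):
    """All circular matches of an IUPAC pattern on a circular reference.

    Returns a sorted list of ``(start, strand)`` with ``start`` the
    top-strand coordinate of the leftmost matched base (for both '+'
    and '-' hits) and ``strand`` in ``{'+', '-'}``.  Matches spanning
    the origin are included; for palindromic patterns the '+' and '-'
    hits at the same locus are both reported.
    """
    if not pattern:
        raise ValueError("empty pattern")
    if len(pattern) >= ref.L:
        raise ValueError("pattern must be shorter than the reference")
    doubled = ref.seq + ref.seq[: len(pattern) - 1]
    hits = set()
    rx = _iupac_regex(pattern)
    for m in rx.finditer(doubled):
        if m.start() < ref.L:
            hits.add((m.start(), "+"))
    if both_strands:
        rx_rc = _iupac_regex(revcomp(pattern))
        for m in rx_rc.finditer(doubled):
            if m.start() < ref.L:
                hits.add((m.start(), "-"))
    return sorted(hits)
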