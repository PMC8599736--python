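"""File formats: FASTA/FASTQ records and the package's tabular outputs.

FASTQ is Sanger Phred+33 only; FASTA output is wrapped at 80 columns.
All tables are tab-separated with a fixed, documented column order so
that reruns with fixed seeds are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FastqRead",
    "FastaRecord",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_tsv",
    "read_consensus_fasta",
    "write_consensus_fasta",
]


class FastqRead(NamedTuple):
    id: str
    seq: str
    qual: str  # Phred+33


class FastaRecord(NamedTuple):
    id: str
    seq: str


def read_fastq(path) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.id, str(rec.seq), qual))
    return out


def write_fastq(path, reads) -> None:
    """``reads`` is an iterable of (id, seq, qual) triples."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fasta(path) -> list[FastaRecord]:
    return [FastaRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(path, records) -> None:
    """``records`` is an iterable of (header, seq); headers written verbatim."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{_wrap(seq)}\n")


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- consensus FASTA dialect -------------------------------------------------
# headers carry the subread count and length: ">id repeats=R len=N"


def write_consensus_fasta(path, consensus_reads) -> None:
    records = [
        (f"{c.id} repeats={c.repeats} len={len(c.seq)}", c.seq)
        for c in consensus_reads
    ]
    write_fasta(path, records)


def read_consensus_fasta(path):
    """Parse consensus FASTA with ``repeats=R`` header tags.

    Returns a list of :class:`cleavemap.consensus.ConsensusRead`; missing
    tags default to ``repeats=1``.
    """
    from .consensus import ConsensusRead

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        repeats = 1
        for tok in rec.description.split()[1:]:
            if tok.startswith("repeats="):
                repeats = int(tok.split("=", 1)[1])
        seq = str(rec.seq)
        out.append(
            ConsensusRead(
                id=rec.id, seq=seq, repeats=repeats, mean_q=float("nan"),
                source_len=len(seq),
            )
        )
    return out


def ensure_exists(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p
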