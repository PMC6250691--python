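"""Promoter scanner for the ACGT-core bZIP binding elements.

bZIP transcription factors preferentially bind the ACGT core and the named
hexamer boxes built around it: G-box (CACGTG), C-box (GACGTC) and A-box
(TACGTA). All four patterns are reverse-complement palindromes, so scanning
the forward strand alone already reports every double-stranded occurrence.

Scanning covers up to 1 kb of sequence upstream of the ORF; longer inputs
are truncated to the 3'-most bases (those nearest the start codon).
Overlapping matches are counted at every start position, and box hits are
also counted as ACGT-core hits (each box contains one core), so the core
and box tallies are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MotifDefinition", "MotifHit", "DEFAULT_MOTIFS", "find_occurrences", "scan_promoters"]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - set("ACGT"):
            raise ValueError(f"motif pattern must be uppercase ACGT, got {self.pattern!r}")


DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("ACGT_core", "ACGT"),
    MotifDefinition("G_box", "CACGTG"),
    MotifDefinition("C_box", "GACGTC"),
    MotifDefinition("A_box", "TACGTA"),
)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    start: int  # 1-based, inclusive
    matched: str


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i + 1}")
    return seq


def find_occurrences(
    sequence: str, motif: MotifDefinition, sequence_id: str = ""
) -> list[MotifHit]:
    """Every (possibly overlapping) occurrence of the motif, 1-based starts.

    Input is case-normalized to uppercase; 'N' is tolerated in the sequence
    but never matches. Any other character raises with its position.
    """
    seq = _validate(sequence)
    pat = motif.pattern
    hits = []
    for i in range(len(seq) - len(pat) + 1):
        if seq[i : i + len(pat)] == pat:
            hits.append(MotifHit(sequence_id, motif.name, i + 1, pat))
    return hits


def scan_promoters(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS,
    upstream_limit: int = 1000,
) -> tuple[pd.DataFrame, list[MotifHit]]:
    """Scan promoter sequences for every motif.

    ``sequences`` maps sequence id -> nucleotide string (e.g. from
    :func:`bzipscreen.io.read_fasta`). Sequences longer than
    ``upstream_limit`` are truncated to their 3'-most ``upstream_limit``
    bases, with a logged note; hit coordinates are then relative to the
    truncated fragment's 5' end.

    Returns (counts, hits): counts is a DataFrame with columns
    sequence_id, motif, count (one row per pair, zero rows included);
    hits is the flat list sorted by (sequence, motif order, start).
    """
    items = sequences.items() if isinstance(sequences, Mapping) else list(sequences)
    rows = []
    all_hits: list[MotifHit] = []
    for seq_id, seq in items:
        if len(seq) > upstream_limit:
            logger.info(
                "sequence %s truncated from %d to %d bp (3'-most bases kept)",
                seq_id, len(seq), upstream_limit,
            )
            seq = seq[-upstream_limit:]
        for motif in motifs:
            hits = find_occurrences(seq, motif, sequence_id=seq_id)
            all_hits.extend(hits)
            rows.append({"sequence_id": seq_id, "motif": motif.name, "count": len(hits)})
    counts = pd.DataFrame(rows, columns=["sequence_id", "motif", "count"])
    return counts, all_hits
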