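"""Synthetic promoter and protein FASTA generators.

Promoters are random nucleotide backgrounds (configurable GC fraction)
with motifs planted at explicit, non-overlapping positions. Because the
background can create additional occurrences by chance, the manifest's
authoritative per-motif counts are recomputed by a brute-force scan of the
finished sequence, not taken from the plant plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..cis import DEFAULT_MOTIFS, MotifDefinition, find_occurrences
from .manifest import GroundTruthManifest, SequenceTruth

__all__ = ["PromoterPlan", "generate_promoters", "generate_proteins"]

_MOTIF_BY_NAME: Mapping[str, MotifDefinition] = {m.name: m for m in DEFAULT_MOTIFS}


@dataclass(frozen=True)
class PromoterPlan:
    """Plant plan for one promoter: (motif name, 1-based start) pairs."""

    sequence_id: str
    plants: tuple[tuple[str, int], ...] = ()


def _check_plan(plan: PromoterPlan, length: int) -> None:
    occupied: list[tuple[int, int]] = []
    for name, start in plan.plants:
        if name not in _MOTIF_BY_NAME:
            raise ValueError(f"{plan.sequence_id}: unknown motif {name!r}")
        pat = _MOTIF_BY_NAME[name].pattern
        end = start + len(pat) - 1
        if start < 1 or end > length:
            raise ValueError(
                f"{plan.sequence_id}: motif {name} at {start} exceeds sequence length {length}"
            )
        for s, e in occupied:
            if start <= e and s <= end:
                raise ValueError(
                    f"{plan.sequence_id}: planted motifs overlap at positions {start}-{end}"
                )
        occupied.append((start, end))


def generate_promoters(
    plans: Sequence[PromoterPlan],
    length: int = 1000,
    gc: float = 0.45,
    seed: int = 0,
    background: bool = True,
) -> tuple[dict[str, str], GroundTruthManifest]:
    """Generate promoter sequences with planted motifs.

    With ``background=False`` the sequence is all-'A' outside the planted
    motifs (useful for exact fixtures); otherwise bases are drawn i.i.d.
    with the given GC fraction. Returns (id -> sequence, manifest); the
    manifest's per-motif ``counts`` are brute-force scan truth.
    """
    if length < 1 and plans:
        for plan in plans:
            if plan.plants:
                raise ValueError("cannot plant motifs in zero-length sequences")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be a fraction, got {gc}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: dict[str, str] = {}
    truths: list[SequenceTruth] = []
    for plan in plans:
        _check_plan(plan, length)
        if background:
            seq = rng.choice(bases, size=length, p=p)
        else:
            seq = np.full(length, "A")
        for name, start in plan.plants:
            pat = _MOTIF_BY_NAME[name].pattern
            seq[start - 1 : start - 1 + len(pat)] = list(pat)
        text = "".join(seq)
        sequences[plan.sequence_id] = text
        planted_counts: dict[str, int] = {}
        for name, _ in plan.plants:
            planted_counts[name] = planted_counts.get(name, 0) + 1
        true_counts = {
            m.name: len(find_occurrences(text, m, plan.sequence_id)) for m in DEFAULT_MOTIFS
        }
        truths.append(SequenceTruth(plan.sequence_id, planted_counts, true_counts))
    manifest = GroundTruthManifest(
        kind="promoters",
        seed=seed,
        config={"length": length, "gc": gc, "background": background, "n": len(plans)},
        sequences=truths,
    )
    return sequences, manifest


def generate_proteins(
    n: int,
    min_length: int = 129,
    max_length: int = 920,
    seed: int = 0,
) -> tuple[dict[str, str], GroundTruthManifest]:
    """Random protein sequences over the 20 standard residues.

    Default length bounds span the range observed across the wheat bZIP
    family (129 to 920 residues). The manifest records each length.
    """
    if min_length < 1 or max_length < min_length:
        raise ValueError("invalid length bounds")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    width = max(2, len(str(n)))
    sequences: dict[str, str] = {}
    truths: list[SequenceTruth] = []
    for i in range(n):
        length = int(rng.integers(min_length, max_length + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        seq_id = f"prot{i + 1:0{width}d}"
        sequences[seq_id] = seq
        truths.append(SequenceTruth(seq_id, {}, {"length": length}))
    manifest = GroundTruthManifest(
        kind="proteins",
        seed=seed,
        config={"n": n, "min_length": min_length, "max_length": max_length},
        sequences=truths,
    )
    return sequences, manifest
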