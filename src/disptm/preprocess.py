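"""Dataset construction: length filtering, redundancy reduction, stats.

The redundancy step is a deterministic greedy clustering on global
pairwise identity (matches / alignment columns), standing in for an
external ortholog-clustering tool: sequences are visited longest first
(ties by id) and join the first representative at or above the identity
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

from .io import ProteinRecord


@dataclass
class DatasetStats:
    """Descriptive statistics of a (possibly filtered) proteome."""

    n_input: int
    n_after_redundancy: int
    n_after_length: int
    mean_length: float
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_after_length <= self.n_after_redundancy <= self.n_input:
            raise ValueError("filter counts must be monotonically non-increasing")
        if self.mean_length <= 0:
            raise ValueError("mean_length must be positive")
        total = sum(self.composition.values())
        if self.composition and abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")


def length_filter(
    records: Sequence[ProteinRecord],
    min_len: int = 50,
    max_len: int = 2000,
) -> list[ProteinRecord]:
    """Keep records with ``min_len <= length <= max_len``, order preserved."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]


def _make_aligner() -> Align.PairwiseAligner:
    # Match 1 / mismatch 0 / linear gap -1; identity = matches / columns.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def global_identity(a: str, b: str) -> float:
    """Global pairwise identity: identities / alignment columns."""
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def redundancy_filter(
    records: Sequence[ProteinRecord],
    identity_cutoff: float = 0.90,
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Greedy identity clustering; returns representatives and clusters.

    Visit order is descending length then ascending id.  A sequence
    joins the first existing representative with identity >= cutoff,
    otherwise it founds a new cluster.
    """
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError(f"identity_cutoff must lie in (0, 1], got {identity_cutoff}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    kept: list[ProteinRecord] = []
    clusters: dict[str, list[str]] = {}
    for rec in ordered:
        for rep in kept:
            if global_identity(rep.sequence, rec.sequence) >= identity_cutoff:
                clusters[rep.id].append(rec.id)
                break
        else:
            kept.append(rec)
            clusters[rec.id] = [rec.id]
    return kept, clusters


def dataset_stats(
    records: Sequence[ProteinRecord],
    n_input: int | None = None,
    n_after_redundancy: int | None = None,
) -> DatasetStats:
    """Mean length and pooled residue composition of a proteome.

    ``n_input``/``n_after_redundancy`` default to ``len(records)`` so
    the type's count invariant holds when no filtering context is given.
    """
    if not records:
        raise ValueError("dataset_stats: empty proteome")
    lengths = np.array([len(r) for r in records])
    pooled = "".join(r.sequence for r in records)
    total = len(pooled)
    counts: dict[str, int] = {}
    for ch in pooled:
        counts[ch] = counts.get(ch, 0) + 1
    composition = {aa: c / total for aa, c in sorted(counts.items())}
    n = len(records)
    return DatasetStats(
        n_input=n if n_input is None else n_input,
        n_after_redundancy=n if n_after_redundancy is None else n_after_redundancy,
        n_after_length=n,
        mean_length=float(lengths.mean()),
        composition=composition,
    )
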