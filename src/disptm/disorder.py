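"""Disorder quantities: per-protein fractions, segments, proteome degree."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import DisorderProfile


@dataclass
class DisorderSummary:
    """Disorder mask summary for one protein.

    ``segments`` are maximal runs of disordered residues as 1-based
    inclusive ``(start, end)`` pairs.
    """

    protein_id: str
    L: int
    Ld_protein: int
    fraction: float
    segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        seg_total = sum(e - s + 1 for s, e in self.segments)
        if seg_total != self.Ld_protein:
            raise ValueError(f"{self.protein_id}: segment lengths != Ld")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"{self.protein_id}: fraction outside [0, 1]")

    def mask(self) -> np.ndarray:
        """Re-expand segments to the boolean per-residue mask."""
        mask = np.zeros(self.L, dtype=bool)
        for s, e in self.segments:
            mask[s - 1 : e] = True
        return mask


def segments_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as 1-based inclusive pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2] + 1, edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def summarize_disorder(
    profile: DisorderProfile, expected_length: int | None = None
) -> DisorderSummary:
    """Mask -> maximal disordered segments and the disorder fraction.

    ``expected_length`` (the protein's sequence length, when known) is
    checked against the profile length.
    """
    calls = np.asarray(profile.calls, dtype=bool)
    if expected_length is not None and calls.size != expected_length:
        raise ValueError(
            f"{profile.protein_id}: profile length {calls.size} != "
            f"sequence length {expected_length}"
        )
    ld = int(calls.sum())
    return DisorderSummary(
        protein_id=profile.protein_id,
        L=int(calls.size),
        Ld_protein=ld,
        fraction=ld / calls.size,
        segments=segments_from_mask(calls),
    )


def proteome_disorder_degree(summaries: Sequence[DisorderSummary]) -> float:
    """Residue-weighted disorder percentage: 100 * sum(Ld) / sum(L)."""
    if not summaries:
        raise ValueError("proteome_disorder_degree: empty input")
    ld = sum(s.Ld_protein for s in summaries)
    ltot = sum(s.L for s in summaries)
    return 100.0 * ld / ltot


def mean_disorder_fraction(summaries: Sequence[DisorderSummary]) -> float:
    """Unweighted mean of per-protein disorder fractions."""
    if not summaries:
        raise ValueError("mean_disorder_fraction: empty input")
    return float(np.mean([s.fraction for s in summaries]))
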