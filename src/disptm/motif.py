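"""Sequence-motif prediction of glycosylation sites.

Two patterns are supported:

* ``NGLY`` — the N-glycosylation sequon Asn-X-Ser/Thr where X is any
  standard residue except Pro.  All (including overlapping) sequons are
  reported, one per acceptor Asn.
* ``OGLY`` — the Hyp-O-glycosylation consensus
  ``[A/S/T/V]-P(1,4)-X(0-10)-[A/S/T/V]-P(1,4)``.  Matching is leftmost,
  non-overlapping, with lazy quantifiers (shortest proline runs and
  spacer that admit a match); scanning resumes after each accepted
  match.  The countable modified residue is the first Pro of the second
  proline run.

The ambiguity residue ``X`` never participates in any match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import AMINO_ACIDS, ProteinRecord, PTMSite

# Sequon: N, then any standard residue except P, then S/T.  Lookahead keeps
# matches overlap-capable (each Asn is independently modifiable).
_NOT_P = AMINO_ACIDS.replace("P", "")
_NGLY_RE = re.compile(rf"N(?=[{_NOT_P}][ST])")

# Lazy quantifiers pin the canonical parse; the trailing P run collapses to
# a single P under laziness, so the match ends at the modified residue.
_OGLY_RE = re.compile(rf"[ASTV]P{{1,4}}?[{AMINO_ACIDS}]{{0,10}}?[ASTV](P{{1,4}}?)")


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence; coordinates are 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    pattern: str  # "OGLY" | "NGLY"
    site_position: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.site_position <= self.end:
            raise ValueError(
                f"{self.protein_id}: inconsistent match coordinates "
                f"({self.start}, {self.site_position}, {self.end})"
            )
        if self.pattern not in ("OGLY", "NGLY"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


def scan_nglyc(record: ProteinRecord) -> list[MotifMatch]:
    """All sequon matches in a record, ascending by start."""
    matches = []
    for m in _NGLY_RE.finditer(record.sequence):
        pos = m.start() + 1
        matches.append(MotifMatch(record.id, pos, pos + 2, "NGLY", pos))
    return matches


def scan_oglyc(record: ProteinRecord) -> list[MotifMatch]:
    """Leftmost non-overlapping O-glycosylation consensus matches."""
    matches = []
    for m in _OGLY_RE.finditer(record.sequence):
        matches.append(
            MotifMatch(record.id, m.start() + 1, m.end(), "OGLY", m.start(1) + 1)
        )
    return matches


_PATTERN_PTM = {"OGLY": ("O-gly", "P"), "NGLY": ("N-gly", "N")}


def sites_from_matches(matches: Iterable[MotifMatch]) -> list[PTMSite]:
    """One PTM site per match at its anchored residue, de-duplicated."""
    sites: list[PTMSite] = []
    seen: set[tuple[str, int, str]] = set()
    for m in matches:
        ptm_type, residue = _PATTERN_PTM[m.pattern]
        key = (m.protein_id, m.site_position, ptm_type)
        if key in seen:
            continue
        seen.add(key)
        sites.append(PTMSite(m.protein_id, m.site_position, residue, ptm_type))
    return sites


def scan_proteome(
    records: Sequence[ProteinRecord], pattern: str = "both"
) -> list[PTMSite]:
    """Scan every record and return de-duplicated sites.

    ``pattern`` is one of ``"ogly"``, ``"ngly"``, ``"both"``.
    """
    if pattern not in ("ogly", "ngly", "both"):
        raise ValueError(f"pattern must be ogly/ngly/both, got {pattern!r}")
    matches: list[MotifMatch] = []
    for rec in records:
        if pattern in ("ogly", "both"):
            matches.extend(scan_oglyc(rec))
        if pattern in ("ngly", "both"):
            matches.extend(scan_nglyc(rec))
    return sites_from_matches(matches)
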