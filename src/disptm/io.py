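"""Readers and writers for the artifact file formats.

Formats handled here:

* FASTA proteomes (via :mod:`Bio.SeqIO`),
* long-format disorder tables (TSV: ``protein_id``, ``position``,
  ``score`` and/or ``call``),
* PTM site tables (TSV: ``protein_id``, ``position``, ``residue``,
  ``ptm_type``),
* species manifests (YAML), and
* generic result tables (TSV).

All positions in files are 1-based and inclusive.  Sequences are
upper-cased on input and may contain the 20 standard residues plus the
ambiguity code ``X``; ``X`` is never PTM-compatible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in sequences (standard + ambiguity code X).
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Modified residue required for each supported PTM type.
PTM_RESIDUES: Mapping[str, str] = {
    "pSer": "S",
    "pThr": "T",
    "pTyr": "Y",
    "O-gly": "P",
    "N-gly": "N",
    "K-ace": "K",
    "K-met": "K",
    "R-met": "R",
}

PTM_TYPES = tuple(PTM_RESIDUES)

CATEGORIES = ("monocot", "dicot", "unspecified")

#: Default score threshold for deriving binary disorder calls (inclusive).
DEFAULT_DISORDER_THRESHOLD = 0.5


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProteinRecord:
    """One amino-acid sequence with optional species/category labels."""

    id: str
    sequence: str
    species: str = ""
    category: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must have length >= 1")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.id}: unknown category {self.category!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(eq=False)
class DisorderProfile:
    """Per-residue disorder annotation for one protein.

    At least one of ``scores`` (reals in [0, 1]) or ``calls`` (booleans,
    True = disordered) must be present.  When only scores are given,
    calls are derived as ``score >= threshold`` (boundary inclusive).
    """

    protein_id: str
    calls: np.ndarray
    scores: np.ndarray | None = None
    threshold: float = DEFAULT_DISORDER_THRESHOLD

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != self.calls.shape:
                raise ValueError(f"{self.protein_id}: scores/calls length mismatch")
            if ((self.scores < 0) | (self.scores > 1)).any():
                raise ValueError(f"{self.protein_id}: disorder scores outside [0, 1]")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.calls.size)

    @classmethod
    def from_scores(
        cls,
        protein_id: str,
        scores: Sequence[float],
        threshold: float = DEFAULT_DISORDER_THRESHOLD,
    ) -> "DisorderProfile":
        scores = np.asarray(scores, dtype=float)
        return cls(protein_id, scores >= threshold, scores, threshold)


@dataclass(frozen=True)
class PTMSite:
    """One predicted modification site (1-based position)."""

    protein_id: str
    position: int
    residue: str
    ptm_type: str

    def __post_init__(self) -> None:
        if self.ptm_type not in PTM_RESIDUES:
            raise ValueError(f"unknown ptm_type {self.ptm_type!r}")
        if self.position < 1:
            raise ValueError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )
        expected = PTM_RESIDUES[self.ptm_type]
        if self.residue != expected:
            raise ValueError(
                f"{self.protein_id}:{self.position}: residue {self.residue!r} "
                f"incompatible with {self.ptm_type} (expected {expected})"
            )


@dataclass
class ManifestEntry:
    """Per-species file locations and category label."""

    category: str
    fasta: Path
    disorder: Path
    sites: dict[str, Path] = field(default_factory=dict)


@dataclass
class SpeciesManifest:
    """Mapping species -> input files, loaded from YAML."""

    entries: dict[str, ManifestEntry]

    def species(self) -> list[str]:
        return list(self.entries)


def read_fasta(
    path: str | os.PathLike,
    species: str = "",
    category: str = "unspecified",
) -> list[ProteinRecord]:
    """Read a FASTA proteome into validated :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id.
    Sequences are upper-cased and a single trailing ``'*'`` stop
    character is stripped.  Duplicate ids, empty files and residues
    outside the 20 standard codes + ``X`` are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        bad = sorted(set(seq) - VALID_RESIDUES)
        if bad:
            raise FormatError(
                f"{path}: record {entry.id!r} contains invalid residues {bad}"
            )
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, seq, species, category))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write records as single-entry-per-protein FASTA."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    if not entries:
        raise ValueError("cannot write an empty FASTA file")
    SeqIO.write(entries, str(path), "fasta")


def _profile_from_rows(pid: str, group: pd.DataFrame, threshold: float) -> DisorderProfile:
    pos = group["position"].to_numpy(dtype=int)
    expected = np.arange(1, len(pos) + 1)
    if not np.array_equal(np.sort(pos), expected):
        raise FormatError(
            f"{pid}: positions must be contiguous 1..L without gaps or duplicates"
        )
    group = group.sort_values("position")
    scores = None
    if "score" in group.columns and group["score"].notna().all():
        scores = group["score"].to_numpy(dtype=float)
        if ((scores < 0) | (scores > 1)).any():
            raise FormatError(f"{pid}: disorder score outside [0, 1]")
    if "call" in group.columns and group["call"].notna().all():
        calls = group["call"].astype(int).to_numpy() != 0
    elif scores is not None:
        calls = scores >= threshold
    else:
        raise FormatError(f"{pid}: need a 'score' or 'call' column")
    return DisorderProfile(pid, calls, scores, threshold)


def read_disorder_table(
    path: str | os.PathLike,
    threshold: float = DEFAULT_DISORDER_THRESHOLD,
) -> list[DisorderProfile]:
    """Read a long-format disorder TSV into per-protein profiles.

    Expected columns: ``protein_id``, ``position`` and at least one of
    ``score``/``call``.  Positions must be contiguous ``1..L`` within
    each protein.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "position"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "score" not in df.columns and "call" not in df.columns:
        raise FormatError(f"{path}: need a 'score' or 'call' column")
    profiles = [
        _profile_from_rows(str(pid), group, threshold)
        for pid, group in df.groupby("protein_id", sort=False)
    ]
    if not profiles:
        raise FormatError(f"{path}: empty disorder table")
    return profiles


def write_disorder_table(
    profiles: Iterable[DisorderProfile], path: str | os.PathLike
) -> None:
    rows = []
    for p in profiles:
        for i in range(len(p)):
            row = {"protein_id": p.protein_id, "position": i + 1}
            if p.scores is not None:
                row["score"] = float(p.scores[i])
            row["call"] = int(p.calls[i])
            rows.append(row)
    write_table(rows, path)


def read_site_table(
    path: str | os.PathLike,
    proteome: Sequence[ProteinRecord] | Mapping[str, str] | None = None,
) -> list[PTMSite]:
    """Read a PTM site TSV; cross-check against a proteome when given.

    Columns: ``protein_id``, ``position``, ``residue``, ``ptm_type``.
    With a proteome, every site's position must fall inside the protein
    and the stated residue must equal the sequence character there.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    for col in ("protein_id", "position", "residue", "ptm_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    seqs: Mapping[str, str] | None
    if proteome is None:
        seqs = None
    elif isinstance(proteome, Mapping):
        seqs = proteome
    else:
        seqs = {r.id: r.sequence for r in proteome}
    sites: list[PTMSite] = []
    for row in df.itertuples(index=False):
        site = PTMSite(str(row.protein_id), int(row.position), row.residue, row.ptm_type)
        if seqs is not None:
            if site.protein_id not in seqs:
                raise FormatError(f"{path}: unknown protein {site.protein_id!r}")
            seq = seqs[site.protein_id]
            if site.position > len(seq):
                raise FormatError(
                    f"{path}: {site.protein_id}:{site.position} beyond "
                    f"sequence length {len(seq)}"
                )
            actual = seq[site.position - 1]
            if actual != site.residue:
                raise FormatError(
                    f"{path}: {site.protein_id}:{site.position} residue "
                    f"mismatch (table {site.residue}, sequence {actual})"
                )
        sites.append(site)
    return sites


def write_site_table(sites: Iterable[PTMSite], path: str | os.PathLike) -> None:
    rows = [
        {
            "protein_id": s.protein_id,
            "position": s.position,
            "residue": s.residue,
            "ptm_type": s.ptm_type,
        }
        for s in sites
    ]
    write_table(rows, path)


def read_manifest(path: str | os.PathLike) -> SpeciesManifest:
    """Load a YAML species manifest; all referenced paths must exist.

    Layout::

        species:
          Arabidopsis:
            category: dicot
            fasta: ara.fasta
            disorder: ara_disorder.tsv
            sites:
              pSer: ara_pser.tsv

    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "species" not in data:
        raise FormatError(f"{path}: manifest must contain a 'species' mapping")
    base = path.parent
    entries: dict[str, ManifestEntry] = {}
    for name, spec in data["species"].items():
        category = spec.get("category")
        if category not in ("monocot", "dicot"):
            raise FormatError(f"{path}: species {name!r} category must be monocot/dicot")
        entry = ManifestEntry(
            category=category,
            fasta=base / spec["fasta"],
            disorder=base / spec["disorder"],
            sites={k: base / v for k, v in spec.get("sites", {}).items()},
        )
        for ptm in entry.sites:
            if ptm not in PTM_RESIDUES:
                raise FormatError(f"{path}: species {name!r} unknown ptm_type {ptm!r}")
        missing = [
            p
            for p in [entry.fasta, entry.disorder, *entry.sites.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FormatError(
                f"{path}: species {name!r} references missing files: "
                + ", ".join(str(m) for m in missing)
            )
        entries[name] = entry
    return SpeciesManifest(entries)


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | os.PathLike,
    float_decimals: int = 4,
) -> None:
    """Write uniform rows as a TSV with a header line.

    Floats are formatted to ``float_decimals`` places (Python's
    round-half-even formatting).  Empty input is an error.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("write_table: rows must be non-empty")
    columns = list(rows[0].keys())
    for row in rows:
        if list(row.keys()) != columns:
            raise ValueError("write_table: rows must share one column set")

    def fmt(value: object) -> str:
        if isinstance(value, float) or isinstance(value, np.floating):
            if np.isnan(value):
                return "NA"
            return f"{value:.{float_decimals}f}"
        return str(value)

    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(row[c]) for c in columns) + "\n")
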