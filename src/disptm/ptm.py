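"""PTM statistics: normalized contents, the Rd/o ratio, site-count bins.

Rd/o = (Nd/Ld) / (No/Lo), where Nd/No are the numbers of sites of one
PTM type falling in disordered/ordered residues and Ld/Lo the total
disordered/ordered residue counts of the proteome.  Rd/o equals 1 when
a PTM shows no structural preference, >1 when it favors disordered
sequence and <1 when it favors ordered sequence.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .disorder import DisorderSummary
from .io import PTMSite, PTM_RESIDUES

#: Pooling threshold for site-count bins: 0..>=4 by default, 0..>=7 for
#: methylation (mirrors the report axes).
DEFAULT_KMAX = 4
KMAX_BY_PTM = {"K-met": 7, "R-met": 7}


def kmax_for(ptm_type: str) -> int:
    return KMAX_BY_PTM.get(ptm_type, DEFAULT_KMAX)


@dataclass
class ContentSummary:
    """Sites per 400 residues for one PTM type."""

    ptm_type: str
    total_sites: int
    total_residues: int
    per_400: float

    def __post_init__(self) -> None:
        if self.per_400 < 0:
            raise ValueError("per_400 must be non-negative")
        if (self.per_400 == 0) != (self.total_sites == 0):
            raise ValueError("per_400 must be zero iff total_sites is zero")


@dataclass
class RdoResult:
    """Disordered/ordered site-density ratio and its components."""

    ptm_type: str
    Nd: int
    No: int
    Ld: int
    Lo: int
    rdo: float
    undefined: bool = False  # True when No == 0 and Nd > 0 (rdo = +inf)


@dataclass
class BinSummary:
    """One site-count bin: population and mean per-protein disorder."""

    ptm_type: str
    bin_label: str
    k_max: int
    n_proteins: int
    mean_disorder: float  # NaN for empty bins


@dataclass
class GroupContrast:
    """Two-group comparison of per-species values (Welch's t stand-in)."""

    category_means: dict[str, float]
    difference: float  # first category mean - second category mean
    t: float
    p_two_tailed: float
    method: str = "welch_t_standin"


class _DisorderIndex:
    """Fast 'is this residue disordered?' lookups from summaries."""

    def __init__(self, summaries: Sequence[DisorderSummary]):
        self._by_id: dict[str, tuple[list[int], list[int], int]] = {}
        for s in summaries:
            starts = [seg[0] for seg in s.segments]
            ends = [seg[1] for seg in s.segments]
            self._by_id[s.protein_id] = (starts, ends, s.L)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def is_disordered(self, protein_id: str, position: int) -> bool:
        starts, ends, L = self._by_id[protein_id]
        if not 1 <= position <= L:
            raise ValueError(
                f"{protein_id}: site position {position} outside 1..{L}"
            )
        i = bisect.bisect_right(starts, position) - 1
        return i >= 0 and position <= ends[i]


def _sites_of_type(sites: Sequence[PTMSite], ptm_type: str) -> list[PTMSite]:
    if ptm_type not in PTM_RESIDUES:
        raise ValueError(f"unknown ptm_type {ptm_type!r}")
    return [s for s in sites if s.ptm_type == ptm_type]


def normalized_content(
    sites: Sequence[PTMSite],
    summaries: Sequence[DisorderSummary],
    ptm_type: str,
) -> ContentSummary:
    """Sites of ``ptm_type`` per 400 residues of the proteome."""
    total_residues = sum(s.L for s in summaries)
    if total_residues == 0:
        raise ValueError("normalized_content: zero total residues")
    n = len(_sites_of_type(sites, ptm_type))
    return ContentSummary(ptm_type, n, total_residues, 400.0 * n / total_residues)


def compute_rdo(
    sites: Sequence[PTMSite],
    summaries: Sequence[DisorderSummary],
    ptm_type: str,
) -> RdoResult:
    """Assign each site to disordered/ordered sequence and form Rd/o.

    A site on a protein absent from ``summaries`` is an error (never
    silently counted as ordered), so Nd + No always equals the number
    of sites of the type and Ld + Lo the number of residues.
    """
    typed = _sites_of_type(sites, ptm_type)
    index = _DisorderIndex(summaries)
    ld = sum(s.Ld_protein for s in summaries)
    lo = sum(s.L for s in summaries) - ld
    if ld == 0 or lo == 0:
        raise ValueError(
            f"degenerate proteome: Ld={ld}, Lo={lo} (both must be positive)"
        )
    nd = 0
    for site in typed:
        if site.protein_id not in index:
            raise ValueError(
                f"site references unknown protein {site.protein_id!r} "
                "(missing disorder annotation)"
            )
        if index.is_disordered(site.protein_id, site.position):
            nd += 1
    no = len(typed) - nd
    assert nd + no == len(typed)
    if no == 0:
        if nd == 0:
            return RdoResult(ptm_type, 0, 0, ld, lo, float("nan"), undefined=True)
        return RdoResult(ptm_type, nd, 0, ld, lo, float("inf"), undefined=True)
    rdo = (nd / ld) / (no / lo)
    return RdoResult(ptm_type, nd, no, ld, lo, rdo)


def bin_by_site_count(
    sites: Sequence[PTMSite],
    summaries: Sequence[DisorderSummary],
    ptm_type: str,
    k_max: int = DEFAULT_KMAX,
) -> list[BinSummary]:
    """Group proteins by their site count: bins 0, 1, ..., >=k_max.

    Every protein in ``summaries`` lands in exactly one bin; empty bins
    are retained with ``n_proteins = 0`` and NaN mean disorder.
    """
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    typed = _sites_of_type(sites, ptm_type)
    known = {s.protein_id for s in summaries}
    counts: dict[str, int] = {s.protein_id: 0 for s in summaries}
    for site in typed:
        if site.protein_id not in known:
            raise ValueError(f"site references unknown protein {site.protein_id!r}")
        counts[site.protein_id] += 1
    fractions: dict[int, list[float]] = {k: [] for k in range(k_max + 1)}
    for s in summaries:
        k = min(counts[s.protein_id], k_max)
        fractions[k].append(s.fraction)
    bins = []
    for k in range(k_max + 1):
        label = str(k) if k < k_max else f">={k_max}"
        vals = fractions[k]
        bins.append(
            BinSummary(
                ptm_type=ptm_type,
                bin_label=label,
                k_max=k_max,
                n_proteins=len(vals),
                mean_disorder=float(np.mean(vals)) if vals else float("nan"),
            )
        )
    assert sum(b.n_proteins for b in bins) == len(summaries)
    return bins


def group_contrast(
    values_by_species: Mapping[str, float],
    categories: Mapping[str, str],
) -> GroupContrast:
    """Compare a per-species statistic between two categories.

    Category order is (monocot, dicot) when present, else sorted names;
    ``difference`` is first minus second.  Significance is Welch's
    unequal-variance t test — a declared stand-in, labelled as such in
    the result's ``method`` field.
    """
    groups: dict[str, list[float]] = {}
    for species, value in values_by_species.items():
        if species not in categories:
            raise ValueError(f"no category for species {species!r}")
        groups.setdefault(categories[species], []).append(float(value))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 categories, got {sorted(groups)}")
    for cat, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"category {cat!r} has <2 species")
    if set(groups) == {"monocot", "dicot"}:
        first, second = "monocot", "dicot"
    else:
        first, second = sorted(groups)
    a, b = groups[first], groups[second]
    means = {first: float(np.mean(a)), second: float(np.mean(b))}
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return GroupContrast(
        category_means=means,
        difference=means[first] - means[second],
        t=float(t),
        p_two_tailed=float(p),
    )
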