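"""Synthetic proteomes with known disorder structure and PTM placement.

Sequences are drawn residue-wise from a composition vector; the
disorder mask alternates geometric-length ordered/disordered blocks
whose means are calibrated so the expected disorder fraction is the
target delta.  Sites of each PTM type are placed independently on
compatible residues with probability ``rate`` on ordered residues and
``rate * rho`` on disordered ones, so the planted enrichment ``rho``
is exactly the expected Rd/o.  A motif-planting mode writes literal
OGLY/NGLY pattern instances at known positions for scanner tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import AMINO_ACIDS, DisorderProfile, ProteinRecord, PTMSite, PTM_RESIDUES

_LETTERS = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")

#: Literal motif instances used by :func:`plant_motifs`; the anchored
#: modified residue sits at ``site_offset`` within the instance.
_MOTIF_INSTANCES = {
    "NGLY": ("NGS", 0, "N", "N-gly"),
    "OGLY": ("APGGSP", 5, "P", "O-gly"),
}


@dataclass
class SynthConfig:
    """Parameters of one synthetic proteome.

    ``length_law`` is ``("fixed", L)``, ``("uniform", a, b)`` or
    ``("lognormal", mu, sigma)`` (the lognormal is truncated to
    [50, 2000]).  ``block_ord`` defaults to the value that makes the
    stationary disorder fraction equal ``disorder_frac``.
    """

    n_proteins: int
    length_law: tuple = ("fixed", 400)
    disorder_frac: float = 0.3
    block_dis: float = 30.0
    block_ord: float | None = None
    ptm_rates: dict[str, float] = field(default_factory=dict)
    enrichment: dict[str, float] = field(default_factory=dict)
    composition: dict[str, float] | None = None
    seed: int = 0
    id_prefix: str = "prot"

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 < self.disorder_frac < 1.0:
            raise ValueError("disorder_frac must lie in (0, 1)")
        if self.block_dis < 1.0:
            raise ValueError("mean disordered-block length must be >= 1")
        derived = self.block_dis * (1.0 - self.disorder_frac) / self.disorder_frac
        if self.block_ord is None:
            self.block_ord = derived
        elif self.block_ord < 1.0 or abs(self.block_ord - derived) > 1e-6:
            raise ValueError(
                "infeasible delta/block combination: need "
                "block_dis/(block_dis+block_ord) == disorder_frac"
            )
        for ptm, rate in self.ptm_rates.items():
            if ptm not in PTM_RESIDUES:
                raise ValueError(f"unknown ptm_type {ptm!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{ptm}: rate must lie in [0, 1]")
            rho = self.enrichment.get(ptm, 1.0)
            if rho < 0:
                raise ValueError(f"{ptm}: enrichment must be >= 0")
            if rate * rho > 1.0:
                raise ValueError(f"{ptm}: rate * enrichment exceeds 1")
        if self.composition is not None:
            if set(self.composition) - set(AMINO_ACIDS):
                raise ValueError("composition keys must be standard residues")
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition sums to {total}, not 1")

    def composition_vector(self) -> np.ndarray:
        if self.composition is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        return np.array([self.composition.get(aa, 0.0) for aa in AMINO_ACIDS])


def plant_like_composition(kr_skew: float = 0.0) -> dict[str, float]:
    """A plant-flavoured composition preset: elevated A/G/P.

    ``kr_skew`` in [-1, 1] shifts probability mass between K and R
    (positive values move K mass toward R, mimicking the lower-K /
    higher-R composition of monocot proteomes).
    """
    if not -1.0 <= kr_skew <= 1.0:
        raise ValueError("kr_skew must lie in [-1, 1]")
    comp = {aa: 1.0 for aa in AMINO_ACIDS}
    for aa in "AGP":
        comp[aa] = 1.6
    shift = comp["K"] * 0.5 * kr_skew
    comp["K"] -= shift
    comp["R"] += shift
    total = sum(comp.values())
    return {aa: v / total for aa, v in comp.items()}


@dataclass
class SynthTruth:
    """Ground truth realized by one :func:`generate` call."""

    planted: dict[str, float]
    Nd: dict[str, int]
    No: dict[str, int]
    Ld: int
    Lo: int
    sites: dict[str, list[PTMSite]]
    masks: dict[str, np.ndarray]


def _draw_lengths(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    kind = config.length_law[0]
    n = config.n_proteins
    if kind == "fixed":
        return np.full(n, int(config.length_law[1]))
    if kind == "uniform":
        a, b = int(config.length_law[1]), int(config.length_law[2])
        if not 1 <= a <= b:
            raise ValueError("uniform length law needs 1 <= a <= b")
        return rng.integers(a, b + 1, size=n)
    if kind == "lognormal":
        mu, sigma = float(config.length_law[1]), float(config.length_law[2])
        lengths = np.empty(n, dtype=int)
        remaining = np.arange(n)
        while remaining.size:
            draw = np.rint(rng.lognormal(mu, sigma, size=remaining.size)).astype(int)
            ok = (draw >= 50) & (draw <= 2000)
            lengths[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
        return lengths
    raise ValueError(f"unknown length law {kind!r}")


def _draw_mask(L: int, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    mask = np.empty(L, dtype=bool)
    state = bool(rng.random() < config.disorder_frac)
    pos = 0
    while pos < L:
        mean = config.block_dis if state else config.block_ord
        block = int(rng.geometric(1.0 / mean))
        mask[pos : pos + block] = state
        pos += block
        state = not state
    return mask


def generate(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], list[DisorderProfile], list[PTMSite], SynthTruth]:
    """Draw a proteome, its disorder profiles and PTM sites, plus truth.

    Deterministic given ``config.seed``; the same config yields
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _draw_lengths(config, rng)
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    total = int(offsets[-1])
    codes = rng.choice(len(AMINO_ACIDS), size=total, p=config.composition_vector())
    pooled_seq = _LETTERS[codes].tobytes().decode()
    gmask = np.empty(total, dtype=bool)
    width = len(str(config.n_proteins))
    ids = [f"{config.id_prefix}{i + 1:0{width}d}" for i in range(config.n_proteins)]
    records, profiles, masks = [], [], {}
    for i, pid in enumerate(ids):
        lo, hi = int(offsets[i]), int(offsets[i + 1])
        mask = _draw_mask(hi - lo, config, rng)
        gmask[lo:hi] = mask
        masks[pid] = mask
        records.append(ProteinRecord(pid, pooled_seq[lo:hi], species="synthetic"))
        profiles.append(DisorderProfile(pid, mask))

    all_sites: list[PTMSite] = []
    truth_sites: dict[str, list[PTMSite]] = {}
    nd: dict[str, int] = {}
    no: dict[str, int] = {}
    for ptm, rate in sorted(config.ptm_rates.items()):
        residue = PTM_RESIDUES[ptm]
        rho = config.enrichment.get(ptm, 1.0)
        eligible = np.flatnonzero(codes == AMINO_ACIDS.index(residue))
        prob = rate * np.where(gmask[eligible], rho, 1.0)
        chosen = eligible[rng.random(eligible.size) < prob]
        sites = []
        for gpos in chosen:
            pi = int(np.searchsorted(offsets, gpos, side="right")) - 1
            sites.append(
                PTMSite(ids[pi], int(gpos - offsets[pi]) + 1, residue, ptm)
            )
        truth_sites[ptm] = sites
        nd[ptm] = int(gmask[chosen].sum())
        no[ptm] = len(sites) - nd[ptm]
        all_sites.extend(sites)

    ld = int(gmask.sum())
    truth = SynthTruth(
        planted={p: config.enrichment.get(p, 1.0) for p in config.ptm_rates},
        Nd=nd,
        No=no,
        Ld=ld,
        Lo=total - ld,
        sites=truth_sites,
        masks=masks,
    )
    return records, profiles, all_sites, truth


def plant_motifs(
    records: Sequence[ProteinRecord],
    pattern: str,
    n_instances: int,
    placement_odds: float = 1.0,
    seed: int = 0,
    profiles: Sequence[DisorderProfile] | Mapping[str, np.ndarray] | None = None,
) -> tuple[list[ProteinRecord], list[PTMSite]]:
    """Overwrite literal motif instances at sampled positions.

    Instances never overlap each other.  With ``profiles``, candidate
    positions whose anchored residue falls in disordered sequence are
    sampled with odds ``placement_odds : 1`` relative to ordered ones.
    Returns the mutated records and the exact expected site list.
    """
    if pattern not in _MOTIF_INSTANCES:
        raise ValueError(f"pattern must be one of {sorted(_MOTIF_INSTANCES)}")
    if placement_odds < 0:
        raise ValueError("placement_odds must be >= 0")
    instance, site_off, residue, ptm_type = _MOTIF_INSTANCES[pattern]
    width = len(instance)
    if profiles is None:
        mask_by_id: Mapping[str, np.ndarray] | None = None
    elif isinstance(profiles, Mapping):
        mask_by_id = profiles
    else:
        mask_by_id = {p.protein_id: np.asarray(p.calls, bool) for p in profiles}

    candidates: list[tuple[int, int]] = []
    weights: list[float] = []
    for ri, rec in enumerate(records):
        mask = mask_by_id.get(rec.id) if mask_by_id is not None else None
        for start in range(len(rec) - width + 1):
            candidates.append((ri, start))
            if mask is None:
                weights.append(1.0)
            else:
                weights.append(placement_odds if mask[start + site_off] else 1.0)
    if n_instances == 0:
        return list(records), []

    rng = np.random.default_rng(seed)
    w = np.asarray(weights)
    keep = w > 0
    order_pool = np.flatnonzero(keep)
    # Weighted sampling without replacement via Gumbel keys.
    keys = np.log(w[keep]) + rng.gumbel(size=keep.sum())
    order = order_pool[np.argsort(-keys)]

    occupied: dict[int, list[tuple[int, int]]] = {}
    placed: list[tuple[int, int]] = []
    for ci in order:
        ri, start = candidates[ci]
        spans = occupied.setdefault(ri, [])
        end = start + width  # exclusive
        if any(start < e and s < end for s, e in spans):
            continue
        spans.append((start, end))
        placed.append((ri, start))
        if len(placed) == n_instances:
            break
    if len(placed) < n_instances:
        raise ValueError(
            f"insufficient space: placed {len(placed)} of {n_instances} instances"
        )

    seqs = [list(r.sequence) for r in records]
    expected: list[PTMSite] = []
    for ri, start in sorted(placed):
        seqs[ri][start : start + width] = instance
        expected.append(
            PTMSite(records[ri].id, start + site_off + 1, residue, ptm_type)
        )
    mutated = [
        ProteinRecord(r.id, "".join(seqs[ri]), r.species, r.category)
        for ri, r in enumerate(records)
    ]
    return mutated, expected
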