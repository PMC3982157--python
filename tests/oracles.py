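"""Independent reference implementations used only by the tests.

These deliberately avoid the library code paths they check: the motif
oracles are brute-force enumerations, and the tail-probability oracle
integrates a hand-written Student-t density numerically.
"""

from __future__ import annotations

import math

from scipy.integrate import quad

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def nglyc_oracle(seq: str) -> list[int]:
    """1-based positions i with seq[i]=N, seq[i+1] not in {P,X}, seq[i+2] in {S,T}."""
    out = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] not in "PX" and seq[i + 2] in "ST":
            out.append(i + 1)
    return out


def _oglyc_match_at(seq: str, i: int) -> tuple[int, int] | None:
    """First (in lazy order: run1 length outer, spacer inner) parse at i.

    Returns (end_index_exclusive, site_index_0based) or None.  The
    second proline run contributes its first P only, matching lazy
    quantifier semantics where the match ends at the earliest admissible
    residue.
    """
    n = len(seq)
    if i >= n or seq[i] not in "ASTV":
        return None
    for p1 in range(1, 5):
        run1 = seq[i + 1 : i + 1 + p1]
        if len(run1) < p1 or run1 != "P" * p1:
            break
        for x in range(0, 11):
            spacer = seq[i + 1 + p1 : i + 1 + p1 + x]
            if len(spacer) < x or any(c not in STANDARD_AA for c in spacer):
                break
            j = i + 1 + p1 + x  # second [ASTV]
            if j + 1 >= n:
                break
            if seq[j] in "ASTV" and seq[j + 1] == "P":
                return (j + 2, j + 1)
    return None


def oglyc_oracle(seq: str) -> list[tuple[int, int, int]]:
    """Leftmost, non-overlapping parses: (start, end, site) 1-based."""
    out = []
    i = 0
    n = len(seq)
    while i < n:
        hit = _oglyc_match_at(seq, i)
        if hit is None:
            i += 1
            continue
        end, site = hit
        out.append((i + 1, end, site + 1))
        i = end
    return out


def t_density(x: float, df: int) -> float:
    """Student's t probability density, written out from the definition."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def t_upper_tail(t: float, df: int) -> float:
    """P(T_df >= t) by adaptive quadrature of the density."""
    value, _ = quad(t_density, t, math.inf, args=(df,))
    return value


def greedy_cluster_oracle(records, cutoff, identity_fn) -> list[str]:
    """Exhaustive all-pairs re-derivation of the greedy representative set.

    Precomputes the full identity matrix, then replays the documented
    greedy order (longest first, ties by id).
    """
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    ident = {}
    for a in ordered:
        for b in ordered:
            if a.id < b.id:
                ident[(a.id, b.id)] = identity_fn(a.sequence, b.sequence)

    def pair(a, b):
        return ident[(a.id, b.id)] if a.id < b.id else ident[(b.id, a.id)]

    reps = []
    for rec in ordered:
        if not any(pair(rep, rec) >= cutoff for rep in reps):
            reps.append(rec)
    return [r.id for r in reps]
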