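"""Pearson correlation of bin index vs mean disorder, with one-tailed p.

Significance follows the classical recipe: given the coefficient r and
the sample size n, t = r * sqrt((n-2) / (1 - r^2)) is referred to
Student's t with n-2 degrees of freedom, and the one-tailed probability
P(T >= |t|) is reported in the direction of the observed sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .ptm import BinSummary


@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    p_one_tailed: float
    direction: int  # sign of r

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(dx @ dy) / (sx * sy)
    return max(-1.0, min(1.0, r))


def one_tailed_p(r: float, n: int) -> float:
    """One-tailed probability of a Pearson coefficient ``r`` at size ``n``.

    Returns P(T_{n-2} >= |t|) with t = r * sqrt((n-2)/(1-r^2)); the
    null (r = 0) gives exactly 0.5.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 (p underflows at perfect correlation)")
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return float(sps.t.sf(t, n - 2))


def correlate_bins(bins: Sequence[BinSummary]) -> CorrelationResult:
    """Correlate bin ordinal (0, 1, ..., k) with bin mean disorder.

    Empty bins are skipped; at least 3 populated bins are required.
    """
    x = [i for i, b in enumerate(bins) if b.n_proteins > 0]
    y = [b.mean_disorder for b in bins if b.n_proteins > 0]
    if len(x) < 3:
        raise ValueError(f"need >=3 populated bins, got {len(x)}")
    r = pearson_r(x, y)
    n = len(x)
    if abs(r) >= 1.0:
        # Perfectly linear bin means: p underflows; report it as 0.
        t = float("inf") if r > 0 else float("-inf")
        return CorrelationResult(r, n, t, 0.0, int(np.sign(r)))
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return CorrelationResult(r, n, t, one_tailed_p(r, n), int(np.sign(r)) or 0)
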