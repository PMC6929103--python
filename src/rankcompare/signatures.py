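"""GSEA-style enrichment scores and total-enrichment-score distances.

The s-length *signature* of a ranked profile x is the pair (p, q) of its
s top-ranked and s bottom-ranked genes.  The enrichment score ES of a
gene set against a profile y is the extreme signed deviation of the
unweighted Kolmogorov-Smirnov running sum walked down y: +1/s for each
member, -1/(N-s) for each non-member.  ES is +1 iff every member
precedes every non-member and -1 in the mirrored case.

The total enrichment score TES_{x,y} = 1 - (ES_y(p) - ES_y(q)) / 2 is a
directed dissimilarity in [0, 2]: 0 when x's top genes sit at y's top
and x's bottom genes at y's bottom (identical orderings), 2 for a full
reversal.  Because TES is asymmetric, pairwise distances symmetrize it:
D_avg(x,y) = (TES_{x,y} + TES_{y,x}) / 2 or D_max(x,y) =
min(TES_{x,y}, TES_{y,x}).

The running sum is accumulated with integer increments (+(N-s) per
member, -s per non-member) and divided by s(N-s) at the end, so the
walk returns to zero exactly and the identities TES(x,x)=0, ES=+/-1 at
the extremes hold without floating-point residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import RankedMatrix, RankedProfile

__all__ = [
    "Signature",
    "EnrichmentResult",
    "DistanceMatrix",
    "DEFAULT_SIGNATURE_LENGTH",
    "extract_signature",
    "enrichment_score",
    "tes",
    "distance_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGNATURE_LENGTH = 250


@dataclass(frozen=True)
class Signature:
    """Top (p) and bottom (q) s-gene lists of one ranked profile."""

    s: int
    top: tuple[str, ...]
    bottom: tuple[str, ...]
    source: str

    def __post_init__(self) -> None:
        if len(self.top) != self.s or len(self.bottom) != self.s:
            raise ValueError("signature lists must both have length s")
        if set(self.top) & set(self.bottom):
            raise ValueError("top and bottom signature lists overlap")


@dataclass(frozen=True)
class EnrichmentResult:
    es_top: float
    es_bottom: float
    tes: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.es_top <= 1.0 and -1.0 <= self.es_bottom <= 1.0):
            raise ValueError("ES out of [-1, 1]")
        if not (0.0 <= self.tes <= 2.0):
            raise ValueError("TES out of [0, 2]")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise profile distances (or, for networks, similarities)."""

    names: tuple[str, ...]
    values: np.ndarray
    method: str
    s: int | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("distance matrix shape does not match names")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if self.method in ("avg", "max"):
            if not np.allclose(np.diag(v), 0.0):
                raise ValueError("distance matrix diagonal is not zero")
            if v.min() < -1e-12 or v.max() > 2.0 + 1e-12:
                raise ValueError("TES-based distances must lie in [0, 2]")


def extract_signature(x: RankedProfile, s: int) -> Signature:
    """The s top-ranked and s bottom-ranked genes of x, in rank order."""
    n = x.n_genes
    if not (1 <= s <= n // 2):
        raise ValueError(f"signature length s={s} out of 1..{n // 2} for N={n}")
    order = x.genes_in_rank_order()
    return Signature(s, tuple(order[:s]), tuple(order[-s:]), x.name)


def _clip_signature_length(s: int, n: int) -> int:
    if s > n // 2:
        clipped = n // 2
        logger.warning("signature length %d clipped to %d (N=%d)", s, clipped, n)
        return clipped
    return s


def enrichment_score(genes: Sequence[str], y: RankedProfile) -> float:
    """Unweighted KS running-sum enrichment of a gene set within y.

    When the largest positive and negative excursions tie in magnitude
    the positive one is reported.
    """
    s = len(genes)
    n = y.n_genes
    if not (1 <= s < n):
        raise ValueError(f"gene-set size must be in 1..{n - 1}, got {s}")
    members = set(genes)
    if len(members) != s:
        raise ValueError("duplicate genes in gene set")
    missing = members - y.universe
    if missing:
        raise ValueError(f"genes not in profile universe: {sorted(missing)[:5]}")
    # integer walk: +(N-s) per member, -s per non-member; ends at 0 exactly
    steps = np.full(n, -s, dtype=np.int64)
    for g in members:
        steps[y.ranks[g] - 1] = n - s
    walk = np.cumsum(steps)
    hi = int(walk.max())
    lo = int(walk.min())
    extreme = hi if hi >= -lo else lo
    return extreme / (s * (n - s))


def tes(x: RankedProfile, y: RankedProfile, s: int) -> EnrichmentResult:
    """Total enrichment score of profile x with respect to profile y."""
    if x.universe != y.universe:
        raise ValueError("profiles are not over the same gene universe")
    sig = extract_signature(x, s)
    es_p = enrichment_score(sig.top, y)
    es_q = enrichment_score(sig.bottom, y)
    return EnrichmentResult(es_p, es_q, 1.0 - (es_p - es_q) / 2.0)


def distance_matrix(
    matrix: RankedMatrix,
    s: int = DEFAULT_SIGNATURE_LENGTH,
    method: str = "avg",
) -> DistanceMatrix:
    """Pairwise enrichment-score distances over a ranked matrix.

    ``avg``: D(x,y) = (TES_{x,y} + TES_{y,x}) / 2.
    ``max``: D(x,y) = min(TES_{x,y}, TES_{y,x}).
    s is clipped to floor(N/2) if necessary (logged).
    """
    if method not in ("avg", "max"):
        raise ValueError(f"unknown method {method!r}: expected 'avg' or 'max'")
    profiles = matrix.profiles
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a distance matrix")
    s = _clip_signature_length(s, matrix.n_genes)
    m = len(profiles)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            t_ij = tes(profiles[i], profiles[j], s).tes
            t_ji = tes(profiles[j], profiles[i], s).tes
            if method == "avg":
                d = (t_ij + t_ji) / 2.0
            else:
                d = min(t_ij, t_ji)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(matrix.names), values, method, s)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    """Square TSV with profile names as both header row and first column."""
    pd.DataFrame(
        dist.values, index=pd.Index(dist.names, name="profile"), columns=dist.names
    ).to_csv(path, sep="\t")


def read_distance_matrix(path, method: str = "avg") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column names differ")
    return DistanceMatrix(
        tuple(str(n) for n in df.columns), df.to_numpy(dtype=float), method
    )
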