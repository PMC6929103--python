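"""Rank-rank hypergeometric overlap (RRHO) maps.

Two ranked profiles over the same N genes are compared on a grid of
paired rank cutoffs (n in list 1, k in list 2, both multiples of a step
size).  Each pixel holds the signed -log10 hypergeometric tail
probability of the observed overlap u between the two top segments:
positive when the overlap exceeds its expectation nk/N (over-tail
P(U >= u)), negative when it falls short (under-tail P(U <= u)).  Tails
are evaluated in log space via log-gamma, so overlaps of
transcriptome-scale lists whose p-values underflow double precision
still map to finite scores.

Rendered with the co-upregulated corner (small cutoffs in both lists)
at the bottom left, so concordant profiles light up the main diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .profiles import RankedProfile

__all__ = [
    "RRHOGrid",
    "default_step_size",
    "signed_log_p",
    "rrho_map",
    "pixel_genes",
    "correct_grid",
    "render_heatmap",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class RRHOGrid:
    step: int
    thresholds_x: tuple[int, ...]
    thresholds_y: tuple[int, ...]
    values: np.ndarray  # signed -log10 p, shape (len(thresholds_x), len(thresholds_y))
    overlaps: np.ndarray  # overlap counts u, same shape
    universe_size: int
    name_x: str = "x"
    name_y: str = "y"
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.thresholds_x), len(self.thresholds_y)):
            raise ValueError("value matrix shape does not match thresholds")
        if self.overlaps.shape != self.values.shape:
            raise ValueError("overlap matrix shape does not match values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in RRHO grid")
        n = np.asarray(self.thresholds_x)[:, None]
        k = np.asarray(self.thresholds_y)[None, :]
        lo = np.maximum(0, n + k - self.universe_size)
        hi = np.minimum(n, k)
        if np.any(self.overlaps < lo) or np.any(self.overlaps > hi):
            raise ValueError("overlap counts violate hypergeometric bounds")


def default_step_size(n_genes: int) -> int:
    """Default bin width: ceil(sqrt(N)), so pixel count grows ~N."""
    if n_genes < 1:
        raise ValueError("universe size must be >= 1")
    return max(1, math.isqrt(n_genes - 1) + 1)


def _log10_tails(N: int, n: int, k: int, u: int) -> tuple[float, float]:
    """(log10 P(U >= u), log10 P(U <= u)) for U ~ Hypergeom(N, n, k).

    Computed as log-sum-exp over log pmf terms from log-gamma; exact tail
    masses far below float underflow keep finite logs.
    """
    lo = max(0, n + k - N)
    hi = min(n, k)
    v = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(k + 1)
        - gammaln(v + 1)
        - gammaln(k - v + 1)
        + gammaln(N - k + 1)
        - gammaln(n - v + 1)
        - gammaln(N - k - n + v + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    upper = logsumexp(logpmf[v >= u])
    lower = logsumexp(logpmf[v <= u])
    # clamp tiny positive drift: each tail is a probability <= 1
    return min(upper, 0.0) / _LN10, min(lower, 0.0) / _LN10


def signed_log_p(N: int, n: int, k: int, u: int) -> float:
    """Signed -log10 hypergeometric tail probability of overlap u.

    Positive (over-tail, P(U >= u)) when u is at or above its expected
    value nk/N, negative (under-tail, P(U <= u)) otherwise.
    """
    if not (0 <= n <= N and 0 <= k <= N):
        raise ValueError(f"cutoffs out of range: n={n}, k={k}, N={N}")
    if not (max(0, n + k - N) <= u <= min(n, k)):
        raise ValueError(
            f"overlap u={u} outside [{max(0, n + k - N)}, {min(n, k)}] for N={N}, n={n}, k={k}"
        )
    log_upper, log_lower = _log10_tails(N, n, k, u)
    if u * N >= n * k:  # u >= expectation nk/N, compared in integers
        return -log_upper
    return log_lower


def rrho_map(x: RankedProfile, y: RankedProfile, step: int | None = None) -> RRHOGrid:
    """Compute the RRHO grid between two ranked profiles.

    Cutoffs run step, 2*step, ... floor(N/step)*step down each list;
    pixel (i, j) holds the signed -log10 tail probability of
    u = |top-n_i of x  intersect  top-k_j of y|.  Trailing genes beyond
    the last full step do not get a partial bin.
    """
    if x.universe != y.universe:
        raise ValueError("profiles are not over the same gene universe")
    N = x.n_genes
    if step is None:
        step = default_step_size(N)
    if not (1 <= step <= N):
        raise ValueError(f"step must be in 1..{N}, got {step}")
    m = N // step
    cuts = tuple(step * (i + 1) for i in range(m))
    genes = list(x.ranks)
    rx = np.array([x.ranks[g] for g in genes])
    ry = np.array([y.ranks[g] for g in genes])
    # counts[i, j] = #genes with rank_x in bin i and rank_y in bin j;
    # cumulative sum gives the overlap u at each cutoff pair
    bx = np.clip((rx - 1) // step, 0, m)  # bin m = beyond the last cutoff
    by = np.clip((ry - 1) // step, 0, m)
    counts = np.zeros((m + 1, m + 1), dtype=np.int64)
    np.add.at(counts, (bx, by), 1)
    overlaps = counts.cumsum(axis=0).cumsum(axis=1)[:m, :m]
    values = np.empty((m, m))
    for i, n in enumerate(cuts):
        for j, k in enumerate(cuts):
            values[i, j] = signed_log_p(N, n, k, int(overlaps[i, j]))
    return RRHOGrid(
        step=step,
        thresholds_x=cuts,
        thresholds_y=cuts,
        values=values,
        overlaps=overlaps,
        universe_size=N,
        name_x=x.name,
        name_y=y.name,
    )


def pixel_genes(
    grid: RRHOGrid, x: RankedProfile, y: RankedProfile, i: int, j: int
) -> list[str]:
    """Genes overlapping in pixel (i, j), ordered by their rank in x."""
    if not (0 <= i < len(grid.thresholds_x) and 0 <= j < len(grid.thresholds_y)):
        raise IndexError(f"pixel ({i}, {j}) out of range for this grid")
    n, k = grid.thresholds_x[i], grid.thresholds_y[j]
    hits = [g for g, r in x.ranks.items() if r <= n and y.ranks[g] <= k]
    hits.sort(key=x.ranks.__getitem__)
    assert len(hits) == int(grid.overlaps[i, j])
    return hits


def correct_grid(grid: RRHOGrid) -> RRHOGrid:
    """Benjamini-Yekutieli adjustment of the two-tailed p-values.

    Each pixel's one-sided tail is doubled (capped at 1) to a two-tailed
    p, the BY step-up is applied across all pixels jointly, and the
    adjusted values are re-expressed as signed -log10 p with the
    original signs.
    """
    if grid.corrected:
        raise ValueError("grid is already corrected")
    flat = grid.values.ravel()
    p_two = np.minimum(1.0, 2.0 * np.power(10.0, -np.abs(flat)))
    p_adj = false_discovery_control(p_two, method="by")
    signs = np.where(flat < 0, -1.0, 1.0)
    adjusted = signs * -np.log10(p_adj)
    return replace(grid, values=adjusted.reshape(grid.values.shape), corrected=True)


def write_grid_tsv(grid: RRHOGrid, values_path, overlaps_path=None) -> None:
    """Write the signed -log10 p matrix (and optionally overlaps) as TSV."""
    import pandas as pd

    idx = pd.Index(grid.thresholds_x, name=f"cutoff_{grid.name_x}")
    cols = [str(t) for t in grid.thresholds_y]
    pd.DataFrame(grid.values, index=idx, columns=cols).to_csv(values_path, sep="\t")
    if overlaps_path is not None:
        pd.DataFrame(grid.overlaps, index=idx, columns=cols).to_csv(
            overlaps_path, sep="\t"
        )


def render_heatmap(grid: RRHOGrid, path, values_tsv=None) -> None:
    """Render the grid as a diverging heat map centered at 0.

    The bottom-left corner compares the top (most upregulated) ends of
    both lists.  The value matrix is also written as TSV next to the
    image (or at ``values_tsv``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = max(float(np.abs(grid.values).max()), 1e-12)
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    im = ax.imshow(
        grid.values.T,
        origin="lower",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        aspect="auto",
        extent=(0, grid.thresholds_x[-1], 0, grid.thresholds_y[-1]),
    )
    ax.set_xlabel(f"rank cutoff in {grid.name_x}")
    ax.set_ylabel(f"rank cutoff in {grid.name_y}")
    label = "signed -log10 p"
    if grid.corrected:
        label += " (BY adjusted)"
    fig.colorbar(im, ax=ax, label=label)
    ax.set_title(f"RRHO: {grid.name_x} vs {grid.name_y}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    if values_tsv is None:
        s = str(path)
        root = s.rsplit(".", 1)[0] if "." in s.rsplit("/", 1)[-1] else s
        values_tsv = root + ".tsv"
    write_grid_tsv(grid, values_tsv)
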