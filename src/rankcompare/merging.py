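"""Prototype ranked list (PRL) construction.

Several ranked profiles describing the same biological state are merged
into one consensus ordering by repeatedly finding the closest pair under
Spearman's footrule, D(x,y) = sum_i |R(i,x) - R(i,y)|, and replacing it
with the Borda mean-rule aggregate (each gene scored by the mean of its
two ranks, then re-ranked).  The greedy closest-pair scheme mirrors
Kruskal's strategy: distances are recomputed among the surviving
profiles after every merge, and the loop ends when one profile — the
PRL — remains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profiles import RankedMatrix, RankedProfile

__all__ = ["MergeTrace", "footrule_distance", "borda_merge", "build_prl"]


@dataclass(frozen=True)
class MergeTrace:
    """The merge schedule: (left name, right name, footrule at merge) per step."""

    steps: tuple[tuple[str, str, int], ...]
    result: RankedProfile

    def __post_init__(self) -> None:
        if any(d < 0 for *_names, d in self.steps):
            raise ValueError("negative footrule distance in trace")


def _check_universe(x: RankedProfile, y: RankedProfile) -> None:
    if x.universe != y.universe:
        raise ValueError(
            f"profiles {x.name!r} and {y.name!r} are not over the same gene universe"
        )


def footrule_distance(x: RankedProfile, y: RankedProfile) -> int:
    """Spearman's footrule: L1 distance between the two rank vectors.

    A metric on permutations of the shared universe; 0 iff the orderings
    are identical, at most floor(N^2/2) for a full reversal.
    """
    _check_universe(x, y)
    return sum(abs(r - y.ranks[g]) for g, r in x.ranks.items())


def borda_merge(
    x: RankedProfile, y: RankedProfile, name: str | None = None
) -> RankedProfile:
    """Borda mean rule: score each gene by the mean of its two ranks,
    re-rank by ascending score (ties by gene id)."""
    _check_universe(x, y)
    # mean of two integers: compare by the (integer) sum, no floats needed
    ordered = sorted(x.ranks, key=lambda g: (x.ranks[g] + y.ranks[g], g))
    if name is None:
        name = f"({x.name}+{y.name})"
    return RankedProfile(name, {g: r for r, g in enumerate(ordered, start=1)})


def build_prl(matrix: RankedMatrix) -> MergeTrace:
    """Merge all profiles of a ranked matrix into a prototype ranked list.

    Each iteration recomputes all pairwise footrule distances among the
    surviving profiles, merges the closest pair (ties broken by the
    lexicographically smallest sorted name pair), and replaces the pair
    with the merged profile named ``(left+right)``.  Deterministic for a
    given input.
    """
    active = list(matrix.profiles)
    steps: list[tuple[str, str, int]] = []
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                d = footrule_distance(a, b)
                key = (d, *sorted((a.name, b.name)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, left, right), i, j = best
        a, b = active[i], active[j]
        if a.name > b.name:
            a, b = b, a
        merged = borda_merge(a, b)
        steps.append((left, right, d))
        active = [p for k, p in enumerate(active) if k not in (i, j)]
        active.append(merged)
    return MergeTrace(tuple(steps), active[0])
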