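"""Differential-expression tables and ranked profiles.

A *ranked profile* is a total ordering of a gene universe obtained by
sorting log2 fold changes in descending order: rank 1 is the most
upregulated gene, rank N the most downregulated.  All downstream
statistics (footrule distances, RRHO maps, enrichment-score distances)
operate on these orderings, never on the fold changes themselves, which
makes profiles from different platforms directly comparable.

Gene identifiers are matched by exact, case-sensitive string equality;
identifier translation and probe collapsing are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "DEProfile",
    "RankedProfile",
    "RankedMatrix",
    "read_de_profile",
    "to_ranked_profile",
    "intersect_profiles",
    "read_ranked_matrix",
    "write_ranked_matrix",
]


@dataclass(frozen=True)
class DEProfile:
    """One differential-expression contrast: gene id -> log2 fold change."""

    name: str
    entries: Mapping[str, float]
    pvalues: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"profile {self.name!r}: no entries")
        for gene, fc in self.entries.items():
            if not math.isfinite(fc):
                raise ValueError(
                    f"profile {self.name!r}: non-finite fold change for gene {gene!r}"
                )
        if self.pvalues is not None:
            for gene, p in self.pvalues.items():
                if not (0.0 < p <= 1.0):
                    raise ValueError(
                        f"profile {self.name!r}: p-value out of (0,1] for gene {gene!r}"
                    )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RankedProfile:
    """A bijection gene id <-> rank in {1..N}; rank 1 = most upregulated."""

    name: str
    ranks: Mapping[str, int]

    def __post_init__(self) -> None:
        n = len(self.ranks)
        if n == 0:
            raise ValueError(f"profile {self.name!r}: empty ranking")
        if set(self.ranks.values()) != set(range(1, n + 1)):
            raise ValueError(
                f"profile {self.name!r}: ranks are not a permutation of 1..{n}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.ranks)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.ranks)

    def genes_in_rank_order(self) -> list[str]:
        """Gene ids sorted from rank 1 (top) to rank N (bottom)."""
        return sorted(self.ranks, key=self.ranks.__getitem__)

    def reversed(self, name: str | None = None) -> "RankedProfile":
        """The profile with every rank r mapped to N+1-r (up/down flipped)."""
        n = self.n_genes
        return RankedProfile(
            name if name is not None else f"{self.name}:rev",
            {g: n + 1 - r for g, r in self.ranks.items()},
        )


@dataclass(frozen=True)
class RankedMatrix:
    """Aligned ranked profiles over one shared, ordered gene universe."""

    universe: tuple[str, ...]
    profiles: tuple[RankedProfile, ...]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("ranked matrix needs at least one profile")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate profile names: {sorted(names)}")
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("duplicate gene ids in universe")
        for p in self.profiles:
            if p.universe != uni:
                raise ValueError(
                    f"profile {p.name!r} gene set differs from the matrix universe"
                )

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.profiles]

    def profile(self, name: str) -> RankedProfile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(f"no profile named {name!r}")


def read_de_profile(
    path,
    gene_col: str = "gene",
    fc_col: str = "log2fc",
    pvalue_col: str | None = None,
    name: str | None = None,
) -> DEProfile:
    """Parse a tab-separated differential-expression table.

    The file must have a header row containing ``gene_col`` and
    ``fc_col``.  Duplicate gene ids and non-numeric fold changes are
    hard errors (the offending gene/row is named), because silently
    dropping rows would shift every downstream rank.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in [gene_col, fc_col] + ([pvalue_col] if pvalue_col else []):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r} (found {list(df.columns)})"
            )
    genes = df[gene_col].astype(str)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    entries: dict[str, float] = {}
    for row_no, (gene, raw) in enumerate(zip(genes, df[fc_col]), start=2):
        try:
            fc = float(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric fold change {raw!r} for gene {gene!r} (line {row_no})"
            ) from None
        if not math.isfinite(fc):
            raise ValueError(
                f"{path}: non-finite fold change for gene {gene!r} (line {row_no})"
            )
        entries[gene] = fc
    pvals = None
    if pvalue_col:
        pvals = {g: float(v) for g, v in zip(genes, df[pvalue_col])}
    if name is None:
        name = getattr(path, "stem", None) or str(path)
    return DEProfile(name, entries, pvals)


def to_ranked_profile(profile: DEProfile) -> RankedProfile:
    """Rank genes by descending fold change; ties broken by gene id.

    Only the ordering of the fold changes matters, so the result is
    invariant under any strictly increasing transform of the values.
    """
    ordered = sorted(profile.entries, key=lambda g: (-profile.entries[g], g))
    return RankedProfile(profile.name, {g: r for r, g in enumerate(ordered, start=1)})


def _as_ranked(p: Union[DEProfile, RankedProfile]) -> RankedProfile:
    return to_ranked_profile(p) if isinstance(p, DEProfile) else p


def intersect_profiles(
    profiles: Sequence[Union[DEProfile, RankedProfile]],
) -> RankedMatrix:
    """Restrict profiles to their common gene universe and re-rank.

    The universe is the set intersection of the gene sets; within each
    profile the relative order of the surviving genes is preserved and
    ranks are re-compacted to 1..|universe|.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to intersect")
    ranked = [_as_ranked(p) for p in profiles]
    universe = set(ranked[0].ranks)
    for p in ranked[1:]:
        universe &= p.universe
    if not universe:
        raise ValueError("empty intersection of gene universes")
    ordered_universe = tuple(sorted(universe))
    out = []
    for p in ranked:
        kept = sorted(universe, key=p.ranks.__getitem__)
        out.append(RankedProfile(p.name, {g: r for r, g in enumerate(kept, start=1)}))
    return RankedMatrix(ordered_universe, tuple(out))


def write_ranked_matrix(matrix: RankedMatrix, path) -> None:
    """Write genes-by-profiles integer ranks as TSV (column ``gene`` first)."""
    df = pd.DataFrame(
        {p.name: [p.ranks[g] for g in matrix.universe] for p in matrix.profiles},
        index=pd.Index(matrix.universe, name="gene"),
    )
    df.to_csv(path, sep="\t")


def read_ranked_matrix(path) -> RankedMatrix:
    """Read a TSV written by :func:`write_ranked_matrix` (round-trip identity)."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: no profiles found")
    n = len(df)
    universe = tuple(str(g) for g in df.index)
    profiles = []
    for col in df.columns:
        try:
            ranks = df[col].astype(int)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: column {col!r} has non-integer ranks") from None
        if set(ranks) != set(range(1, n + 1)):
            raise ValueError(f"{path}: column {col!r} is not a permutation of 1..{n}")
        profiles.append(RankedProfile(str(col), dict(zip(universe, ranks))))
    return RankedMatrix(universe, tuple(profiles))
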