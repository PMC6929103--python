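import math

import pytest

from rankcompare import (
    FixtureSpec,
    GroupSpec,
    RankedMatrix,
    RankedProfile,
    simulate_profiles,
)


def ranked(name: str, gene_order: str) -> RankedProfile:
    """Build a profile from a string of single-letter genes in rank order."""
    return RankedProfile(name, {g: r for r, g in enumerate(gene_order, start=1)})


def oracle_log10_tails(N: int, n: int, k: int, u: int) -> tuple[float, float]:
    """Exact-combinatorics hypergeometric tails, log10, via big-integer sums.

    Independent of the log-gamma implementation: tail masses are exact
    integer ratios sum C(k,v) C(N-k,n-v) / C(N,n), logged at the end.
    """
    total = math.comb(N, n)
    lo, hi = max(0, n + k - N), min(n, k)
    upper = sum(math.comb(k, v) * math.comb(N - k, n - v) for v in range(u, hi + 1))
    lower = sum(math.comb(k, v) * math.comb(N - k, n - v) for v in range(lo, u + 1))
    return math.log10(upper) - math.log10(total), math.log10(lower) - math.log10(total)


@pytest.fixture(scope="session")
def two_group_sim():
    """Two groups of 5 noisy replicates over independent base orderings."""
    spec = FixtureSpec(
        n_genes=200,
        groups=(GroupSpec("A", 5, 0.05), GroupSpec("B", 5, 0.05)),
        seed=42,
    )
    return simulate_profiles(spec)


@pytest.fixture
def small_matrix() -> RankedMatrix:
    p1 = ranked("p1", "ABCDEF")
    p2 = ranked("p2", "ABCDFE")
    p3 = ranked("p3", "FEDCBA")
    return RankedMatrix(tuple("ABCDEF"), (p1, p2, p3))
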