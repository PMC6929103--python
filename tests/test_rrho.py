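import math

import numpy as np
import pytest

from rankcompare import (
    RankedProfile,
    correct_grid,
    default_step_size,
    pixel_genes,
    render_heatmap,
    rrho_map,
    signed_log_p,
)

from .conftest import oracle_log10_tails, ranked


def random_profile(name, n, rng):
    order = rng.permutation(n)
    return RankedProfile(name, {f"g{i}": int(order[i]) + 1 for i in range(n)})


class TestDefaultStepSize:
    @pytest.mark.parametrize("n,expected", [(100, 10), (1, 1), (101, 11), (2, 2)])
    def test_ceil_sqrt(self, n, expected):
        assert default_step_size(n) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            default_step_size(0)


class TestSignedLogP:
    def test_complete_overlap_is_positive(self):
        # P(U >= 5) = 1/C(10,5) = 1/252
        assert signed_log_p(10, 5, 5, 5) == pytest.approx(math.log10(252), abs=1e-9)

    def test_zero_overlap_is_negative(self):
        assert signed_log_p(10, 5, 5, 0) == pytest.approx(-math.log10(252), abs=1e-9)

    def test_whole_list_overlap_certain(self):
        assert signed_log_p(20, 20, 7, 7) == pytest.approx(0.0, abs=1e-12)

    def test_bound_violation(self):
        with pytest.raises(ValueError, match="outside"):
            signed_log_p(10, 5, 5, 6)

    def test_matches_exact_combinatorics_oracle_sample(self):
        """Log-gamma tails vs big-integer tail sums on a small universe."""
        for N in (7, 12, 19):
            for n in range(1, N + 1):
                for k in range(1, N + 1):
                    for u in range(max(0, n + k - N), min(n, k) + 1):
                        log_up, log_lo = oracle_log10_tails(N, n, k, u)
                        expect = -log_up if u * N >= n * k else log_lo
                        assert signed_log_p(N, n, k, u) == pytest.approx(
                            expect, abs=1e-9
                        )

    def test_two_tail_consistency_on_oracle(self):
        """P(U>=u) + P(U<=u-1) = 1, exactly, in integer arithmetic."""
        N = 15
        for n in range(1, N + 1):
            for k in range(1, N + 1):
                lo, hi = max(0, n + k - N), min(n, k)
                total = math.comb(N, n)
                for u in range(lo + 1, hi + 1):
                    upper = sum(
                        math.comb(k, v) * math.comb(N - k, n - v)
                        for v in range(u, hi + 1)
                    )
                    lower = sum(
                        math.comb(k, v) * math.comb(N - k, n - v)
                        for v in range(lo, u)
                    )
                    assert upper + lower == total

    def test_deep_tail_stays_finite(self):
        # top-500 vs top-500 complete overlap out of 10000: far below underflow
        v = signed_log_p(10000, 500, 500, 500)
        assert np.isfinite(v) and v > 300


class TestRRHOMap:
    def test_self_comparison_peaks_on_diagonal(self):
        rng = np.random.default_rng(0)
        x = random_profile("x", 120, rng)
        grid = rrho_map(x, x, step=10)
        diag = np.diag(grid.values)
        assert np.all(diag >= 0)
        assert grid.values.max() == pytest.approx(diag.max())
        # diagonal overlap is complete: u = n at every diagonal pixel
        assert np.array_equal(np.diag(grid.overlaps), np.array(grid.thresholds_x))

    def test_step_equal_n_is_certain(self):
        x = ranked("x", "ABCDE")
        grid = rrho_map(x, x, step=5)
        assert grid.values.shape == (1, 1)
        assert grid.overlaps[0, 0] == 5
        assert grid.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_reversal_depletes_top_top_corner(self):
        rng = np.random.default_rng(1)
        x = random_profile("x", 100, rng)
        grid = rrho_map(x, x.reversed(), step=10)
        assert grid.overlaps[0, 0] == 0
        assert grid.values[0, 0] <= 0

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(2)
        x = random_profile("x", 90, rng)
        y = random_profile("y", 90, rng)
        gxy = rrho_map(x, y, step=9)
        gyx = rrho_map(y, x, step=9)
        np.testing.assert_allclose(gxy.values, gyx.values.T, atol=1e-12)
        assert np.array_equal(gxy.overlaps, gyx.overlaps.T)

    def test_independent_profiles_rarely_significant(self):
        rng = np.random.default_rng(3)
        x = random_profile("x", 400, rng)
        y = random_profile("y", 400, rng)
        grid = rrho_map(x, y, step=20)
        frac = float(np.mean(np.abs(grid.values) > -math.log10(0.05)))
        assert frac < 0.15

    def test_mismatched_universe_and_bad_step(self):
        x = ranked("x", "ABC")
        with pytest.raises(ValueError, match="universe"):
            rrho_map(x, ranked("y", "ABD"), step=1)
        with pytest.raises(ValueError, match="step"):
            rrho_map(x, x.reversed(), step=4)


class TestPixelGenes:
    def test_self_pixel_is_top_bin(self):
        x = ranked("x", "FEDCBA")
        grid = rrho_map(x, x, step=2)
        assert pixel_genes(grid, x, x, 0, 0) == ["F", "E"]

    def test_disjoint_bins_empty(self):
        x = ranked("x", "ABCDEF")
        y = x.reversed()
        grid = rrho_map(x, y, step=2)
        assert pixel_genes(grid, x, y, 0, 0) == []

    def test_matches_brute_force_enumeration(self):
        x = ranked("x", "ABCDEF")
        y = ranked("y", "BDACFE")
        grid = rrho_map(x, y, step=2)
        for i in range(3):
            for j in range(3):
                n, k = grid.thresholds_x[i], grid.thresholds_y[j]
                top_x = set(x.genes_in_rank_order()[:n])
                top_y = set(y.genes_in_rank_order()[:k])
                expect = sorted(top_x & top_y, key=x.ranks.__getitem__)
                assert pixel_genes(grid, x, y, i, j) == expect

    def test_out_of_range_pixel(self):
        x = ranked("x", "ABCD")
        grid = rrho_map(x, x, step=2)
        with pytest.raises(IndexError):
            pixel_genes(grid, x, x, 2, 0)


class TestCorrectGrid:
    def test_single_pixel_unchanged_up_to_two_tailing(self):
        x = ranked("x", "ABCDE")
        grid = rrho_map(x, x, step=5)
        corrected = correct_grid(grid)
        raw_two = min(1.0, 2 * 10 ** (-abs(grid.values[0, 0])))
        assert abs(corrected.values[0, 0]) == pytest.approx(-math.log10(raw_two))
        assert corrected.corrected

    def test_double_correction_rejected(self):
        x = ranked("x", "ABCDE")
        corrected = correct_grid(rrho_map(x, x, step=5))
        with pytest.raises(ValueError, match="already corrected"):
            correct_grid(corrected)

    def test_matches_by_step_up_oracle(self):
        """BY on known p-values, checked against the direct formula."""
        from scipy.stats import false_discovery_control

        p = np.array([0.001, 0.01, 0.02, 0.04])
        m = len(p)
        c_m = sum(1.0 / i for i in range(1, m + 1))
        # step-up: adj_i = min over j>=i of min(1, m*c_m*p_(j)/j)
        raw = m * c_m * p / np.arange(1, m + 1)
        expect = np.minimum.accumulate(raw[::-1])[::-1].clip(max=1.0)
        np.testing.assert_allclose(false_discovery_control(p, method="by"), expect)

    def test_signs_preserved(self):
        rng = np.random.default_rng(4)
        x = random_profile("x", 80, rng)
        y = random_profile("y", 80, rng)
        grid = rrho_map(x, y, step=8)
        corrected = correct_grid(grid)
        neg = grid.values < 0
        assert np.all(corrected.values[neg] <= 0)
        assert np.all(corrected.values[~neg] >= 0)


class TestRenderHeatmap:
    def test_writes_png_and_value_tsv(self, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(5)
        x = random_profile("x", 60, rng)
        grid = rrho_map(x, x, step=10)
        png = tmp_path / "map.png"
        render_heatmap(grid, png)
        assert png.exists() and png.stat().st_size > 0
        tsv = pd.read_csv(tmp_path / "map.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(tsv.to_numpy(), grid.values)
        # identical profiles: strongly positive diagonal in the exported matrix
        assert np.all(np.diag(tsv.to_numpy())[:-1] > -math.log10(0.05))

    def test_reversed_profiles_corner_structure(self, tmp_path):
        rng = np.random.default_rng(6)
        x = random_profile("x", 100, rng)
        grid = rrho_map(x, x.reversed(), step=10)
        render_heatmap(grid, tmp_path / "rev.png")
        v = grid.values
        # an exact reversal pins every overlap at its minimum: nothing is
        # enriched above chance, and the map maximum (0, a certain tail)
        # sits in the anti-diagonal corners where one cutoff spans the list
        assert v.max() == pytest.approx(0.0, abs=1e-12)
        assert v[0, -1] == pytest.approx(v.max(), abs=1e-12)
        assert v[-1, 0] == pytest.approx(v.max(), abs=1e-12)
        assert v[0, 0] < 0
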