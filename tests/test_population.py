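"""Unit and property tests for the independent-expression null model."""

import itertools

import numpy as np
import pytest
from scipy import stats

from coexsim import (
    CellPopulationMatrix,
    ModelSpec,
    TransmitterPanel,
    assign_cells,
    coexpression_ratios,
    draw_count,
    run_model,
    simulate_population,
)


class TestDrawCount:
    def test_zero_sd_rounds_the_mean(self, rng):
        assert draw_count(12.16, 0.0, 360, rng) == 12
        assert draw_count(12.5, 0.0, 360, rng) == 13

    def test_clipped_to_population(self, rng):
        for _ in range(200):
            assert 0 <= draw_count(150.66, 16.79, 360, rng) <= 360
        # extreme sd forces both bounds to be exercised
        draws = [draw_count(180.0, 1000.0, 360, rng) for _ in range(300)]
        assert min(draws) == 0 and max(draws) == 360

    def test_mean_converges_to_normal_mean(self, rng):
        # CLT oracle: sample mean of round(Normal(150.66, 16.79)) draws
        n = 10_000
        draws = np.array([draw_count(150.66, 16.79, 360, rng) for _ in range(n)])
        assert abs(draws.mean() - 150.66) <= 3 * 16.79 / np.sqrt(n)

    def test_mean_above_population_is_an_error(self, rng):
        with pytest.raises(ValueError, match="exceeds population"):
            draw_count(400.0, 0.0, 360, rng)


class TestAssignCells:
    def test_full_and_empty_subsets(self, rng):
        assert sorted(assign_cells(360, 360, rng)) == list(range(360))
        assert assign_cells(360, 0, rng).size == 0

    def test_count_above_population_is_an_error(self, rng):
        with pytest.raises(ValueError, match="exceeds n_cells"):
            assign_cells(10, 11, rng)

    def test_uniform_inclusion_frequency(self, rng):
        # each cell should be included with probability count/n_cells
        n, count, reps = 360, 12, 10_000
        hits = np.zeros(n)
        for _ in range(reps):
            hits[assign_cells(n, count, rng)] += 1
        p = count / n
        se = np.sqrt(p * (1 - p) / reps)
        assert np.all(np.abs(hits / reps - p) <= 5 * se)

    def test_exact_subset_size(self, rng):
        for count in (0, 1, 7, 20):
            idx = assign_cells(20, count, rng)
            assert idx.size == count and np.unique(idx).size == count


class TestSimulatePopulation:
    def test_deterministic_counts_with_zero_sd(self, rng):
        panel = TransmitterPanel(("X",), (5.0,), (0.0,), population_mean=10.0)
        matrix = simulate_population(panel, rng)
        assert matrix.counts.tolist() == [5]

    def test_saturated_counts_force_full_overlap(self, rng):
        panel = TransmitterPanel(("X", "Y"), (360.0, 360.0), (0.0, 0.0), 360.0)
        matrix = simulate_population(panel, rng)
        assert matrix.membership.all()

    def test_column_sums_match_drawn_counts_within_clip_bounds(self, panel, rng):
        matrix = simulate_population(panel, rng)
        assert matrix.n_cells == 360
        counts = matrix.counts
        for name, mean, sd in zip(panel.transmitters, panel.count_mean, panel.count_sd):
            c = counts[panel.index(name)]
            assert 0 <= c <= 360
            if sd == 0:
                assert c == round(mean)


class TestCoexpressionRatios:
    def test_identity_and_disjoint(self):
        m = np.zeros((6, 2), dtype=bool)
        m[:3, 0] = True
        m[3:5, 1] = True
        table = coexpression_ratios(CellPopulationMatrix(m, ("X", "Y")))
        assert table.ratio_of("X", "X") == 1.0
        assert table.ratio_of("X", "Y") == 0.0
        assert table.overlap_of("X", "Y") == 0

    def test_empty_source_is_undefined(self):
        m = np.zeros((4, 2), dtype=bool)
        m[:2, 1] = True
        table = coexpression_ratios(CellPopulationMatrix(m, ("X", "Y")))
        assert np.isnan(table.ratio_of("X", "Y"))
        assert table.ratio_of("Y", "X") == 0.0

    def test_overlap_is_symmetric_and_bounded(self, panel, rng):
        # inclusion-exclusion bounds on every pairwise overlap
        matrix = simulate_population(panel, rng)
        table = coexpression_ratios(matrix)
        n = matrix.n_cells
        counts = table.source_count
        for i, j in itertools.combinations(range(len(panel.transmitters)), 2):
            o = table.overlap[i, j]
            assert o == table.overlap[j, i]
            assert o <= min(counts[i], counts[j])
            assert o >= counts[i] + counts[j] - n


class TestRunModel:
    def test_seed_determinism_bit_identical(self, tiny_panel):
        spec = ModelSpec(panel=tiny_panel, n_iterations=17, seed=99)
        a = run_model(spec)
        b = run_model(spec)
        np.testing.assert_array_equal(a.mean_ratio, b.mean_ratio)
        np.testing.assert_array_equal(a.sd_ratio, b.sd_ratio)
        np.testing.assert_array_equal(a.n_defined, b.n_defined)

    def test_forced_overlap_is_exact(self, tiny_panel):
        # counts 10 and 4 in a 10-cell population: ratios are forced
        result = run_model(ModelSpec(panel=tiny_panel, n_iterations=50, seed=1))
        assert result.mean_of("B", "A") == 1.0
        assert result.mean_of("A", "B") == pytest.approx(0.4)
        assert result.sd_of("A", "B") == pytest.approx(0.0, abs=1e-6)

    def test_mean_ratio_matches_hypergeometric_expectation(self, panel):
        # E[ratio X->Y] = E[n_Y]/N under independent uniform assignment
        result = run_model(ModelSpec(panel=panel, n_iterations=4000, seed=7))
        n = 360
        i = panel.index("TK")
        j = panel.index("MIP")
        expected = panel.count_mean[j] / n  # sd=16.79 ~ symmetric, far from bounds
        se = result.sd_of("TK", "MIP") / np.sqrt(result.n_defined[i, j])
        assert abs(result.mean_of("TK", "MIP") - expected) <= 4 * se

    def test_small_population_matches_exhaustive_enumeration(self):
        # brute-force oracle: average ratio over all subset assignments at N=8
        n, nx, ny = 8, 3, 4
        cells = range(n)
        total = 0.0
        count = 0
        for xs in itertools.combinations(cells, nx):
            sx = set(xs)
            for ys in itertools.combinations(cells, ny):
                total += len(sx & set(ys)) / nx
                count += 1
        exact = total / count
        panel = TransmitterPanel(("X", "Y"), (float(nx), float(ny)), (0.0, 0.0), float(n))
        result = run_model(ModelSpec(panel=panel, n_iterations=8000, seed=3))
        se = result.sd_of("X", "Y") / np.sqrt(8000)
        assert abs(result.mean_of("X", "Y") - exact) <= 4 * se

    def test_overlap_distribution_is_hypergeometric_at_n20(self):
        # chi-squared goodness of fit of the Monte Carlo overlap distribution
        n, nx, ny, iters = 20, 8, 12, 10_000
        panel = TransmitterPanel(("X", "Y"), (float(nx), float(ny)), (0.0, 0.0), float(n))
        from coexsim.population import _iteration_rng
        from coexsim.rules import realize_population

        overlaps = np.empty(iters, dtype=int)
        for it in range(iters):
            matrix, _, _ = realize_population(panel, (), _iteration_rng(11, it))
            overlaps[it] = int((matrix.membership[:, 0] & matrix.membership[:, 1]).sum())
        lo, hi = max(0, nx + ny - n), min(nx, ny)
        observed = np.bincount(overlaps - lo, minlength=hi - lo + 1)
        expected = stats.hypergeom.pmf(np.arange(lo, hi + 1), n, nx, ny) * iters
        keep = expected >= 5  # merge thin tails into neighbours
        obs = np.concatenate([[observed[~keep].sum()], observed[keep]])
        exp = np.concatenate([[expected[~keep].sum()], expected[keep]])
        if exp[0] == 0:
            obs, exp = obs[1:], exp[1:]
        chi2 = ((obs - exp) ** 2 / exp).sum()
        pvalue = stats.chi2.sf(chi2, df=len(exp) - 1)
        assert pvalue > 0.01

    def test_undefined_pairs_are_skipped_not_zeroed(self):
        panel = TransmitterPanel(("X", "Y"), (0.0, 3.0), (0.0, 0.0), 6.0)
        result = run_model(ModelSpec(panel=panel, n_iterations=20, seed=5))
        assert np.isnan(result.mean_of("X", "Y"))
        assert result.n_defined[0, 1] == 0
        assert result.mean_of("Y", "X") == 0.0
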