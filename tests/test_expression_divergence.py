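"""Pair correlations, random-pair nulls, KS comparisons and level stratification."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from markdiv.expression_divergence import (ExpressionMatrix,
                                           apply_measurability_mask,
                                           class_distribution_summary,
                                           fisher_transform,
                                           joint_levels_and_quintiles,
                                           level_correlation_regression,
                                           pair_correlation, pair_correlations,
                                           ks_two_sided, random_pair_null)
from markdiv.mark_classes import ParalogPair
from oracles import oracle_ks_d


def _matrix(rows: dict) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(data=df)


class TestPairCorrelation:
    def test_perfect_linear(self):
        m = _matrix({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
        pc = pair_correlation(ParalogPair("a", "b"), m)
        assert pc.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        m = _matrix({"a": [1, 2, 3, 4], "b": [8, 6, 4, 2]})
        assert pair_correlation(ParalogPair("a", "b"), m).r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        m = _matrix({"a": [1, 2, 3, 4], "b": [5, 5, 5, 5]})
        pc = pair_correlation(ParalogPair("a", "b"), m)
        assert not pc.defined and math.isnan(pc.r)

    def test_missing_gene_skipped(self):
        m = _matrix({"a": [1, 2, 3]})
        got, skipped = pair_correlations([ParalogPair("a", "zzz")], m)
        assert got == [] and skipped == ["a|zzz"]

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            _matrix({"a": [1, float("nan"), 3]})


class TestMeasurabilityMask:
    def test_retention_percentages(self):
        pairs = [ParalogPair(f"a{i}", f"b{i}", "both") for i in range(100)]
        mask = {f"a{i}" for i in range(100)} | {f"b{i}" for i in range(71)}
        kept, retention = apply_measurability_mask(pairs, mask)
        assert len(kept) == 71
        assert retention == {"both": 71}

    def test_full_mask(self):
        pairs = [ParalogPair("a", "b", "none")]
        kept, retention = apply_measurability_mask(pairs, {"a", "b"})
        assert kept == pairs and retention == {"none": 100}

    def test_partial_pair_dropped(self):
        pairs = [ParalogPair("a", "b", "none")]
        kept, _ = apply_measurability_mask(pairs, {"a"})
        assert kept == []


class TestRandomPairNull:
    def test_median_near_zero_for_independent_profiles(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(data=pd.DataFrame(
            rng.standard_normal((500, 120)),
            index=[f"g{i}" for i in range(500)]))
        null = random_pair_null(m, n_draws=10_000, seed=1)
        assert abs(null.median) < 0.02
        assert np.all(null.values >= -1) and np.all(null.values <= 1)

    def test_reproducible(self):
        rng = np.random.default_rng(3)
        m = ExpressionMatrix(data=pd.DataFrame(
            rng.standard_normal((20, 10)), index=[f"g{i}" for i in range(20)]))
        n1 = random_pair_null(m, n_draws=50, seed=42)
        n2 = random_pair_null(m, n_draws=50, seed=42)
        np.testing.assert_array_equal(n1.values, n2.values)
        n3 = random_pair_null(m, n_draws=50, seed=43)
        assert not np.array_equal(n1.values, n3.values)

    def test_shared_profile_gives_unit_correlation(self):
        base = list(np.arange(6.0))
        m = _matrix({f"g{i}": base for i in range(5)})
        null = random_pair_null(m, n_draws=10, seed=0)
        np.testing.assert_allclose(null.values, 1.0)

    def test_too_few_genes(self):
        m = _matrix({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            random_pair_null(m, n_draws=5, seed=0)


class TestKS:
    def test_identical_samples(self):
        res = ks_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.d == 0.0 and res.p_value == 1.0

    def test_disjoint_supports(self):
        res = ks_two_sided([0.0, 1.0], [5.0, 6.0])
        assert res.d == 1.0

    def test_d_matches_ecdf_oracle_small_samples(self):
        # exhaustive oracle for every random sample pair of sizes <= 8
        rng = np.random.default_rng(17)
        for _ in range(200):
            na, nb = rng.integers(1, 9, size=2)
            a = rng.integers(0, 5, size=na).astype(float)  # ties likely
            b = rng.integers(0, 5, size=nb).astype(float)
            res = ks_two_sided(a, b)
            assert res.d == pytest.approx(oracle_ks_d(a, b)), (a, b)

    def test_p_close_to_permutation_estimate(self):
        # asymptotic p vs a seeded permutation estimate, in the large-sample
        # regime where the asymptotic null applies
        rng = np.random.default_rng(7)
        n = 200
        a = rng.normal(0, 1, n)
        b = rng.normal(0.11, 1, n)
        res = ks_two_sided(a, b)
        pool = np.concatenate([a, b])
        pts = np.sort(pool)
        count = 0
        B = 20_000
        for _ in range(B):
            perm = rng.permutation(pool)
            x, y = np.sort(perm[:n]), np.sort(perm[n:])
            d = np.max(np.abs(
                np.searchsorted(x, pts, side="right") / n
                - np.searchsorted(y, pts, side="right") / n))
            if d >= res.d - 1e-12:
                count += 1
        perm_p = count / B
        assert res.p_value == pytest.approx(perm_p, rel=0.10)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_two_sided([], [1.0])


class TestClassSummary:
    def test_median_conventions(self):
        summary = class_distribution_summary({"x": [0.1, 0.2, 0.3],
                                              "y": [0.1, 0.2, 0.3, 0.4]})
        assert summary["classes"]["x"]["median"] == pytest.approx(0.2)
        assert summary["classes"]["y"]["median"] == pytest.approx(0.25)
        assert "x_vs_y" in summary["ks"]

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            class_distribution_summary({"x": []})


class TestLevelsAndQuintiles:
    def _pairs_matrix(self, n_pairs, rng):
        rows, pairs = {}, []
        for k in range(n_pairs):
            rows[f"a{k}"] = rng.uniform(0, 10, size=5)
            rows[f"b{k}"] = rng.uniform(0, 10, size=5)
            pairs.append(ParalogPair(f"a{k}", f"b{k}", "none"))
        return pairs, _matrix(rows)

    def test_joint_level_is_summed_intensity(self):
        m = _matrix({"a": [1, 2, 3, 4], "b": [2, 4, 6, 2]})
        (lvl,) = joint_levels_and_quintiles([ParalogPair("a", "b")], m)
        assert lvl.joint_level == pytest.approx(24.0)

    @pytest.mark.parametrize("n_pairs", [100, 101, 37])
    def test_bin_sizes_equal_within_one(self, n_pairs):
        rng = np.random.default_rng(n_pairs)
        pairs, m = self._pairs_matrix(n_pairs, rng)
        levels = joint_levels_and_quintiles(pairs, m)
        sizes = np.bincount([l.quintile for l in levels], minlength=6)[1:]
        assert sizes.sum() == n_pairs
        assert sizes.max() - sizes.min() <= 1
        # deterministic: bins ordered by level
        by_bin = {}
        for l in levels:
            by_bin.setdefault(l.quintile, []).append(l.joint_level)
        for q in range(1, 5):
            assert max(by_bin[q]) <= min(by_bin[q + 1])


class TestFisherTransform:
    def test_values(self):
        assert fisher_transform(0.0) == 0.0
        assert fisher_transform(0.5) == pytest.approx(math.log(3.0))
        assert fisher_transform(-0.5) == pytest.approx(-math.log(3.0))
        assert math.isinf(fisher_transform(1.0))

    def test_monotone(self):
        rs = np.linspace(-0.99, 0.99, 50)
        zs = [fisher_transform(r) for r in rs]
        assert all(a < b for a, b in zip(zs, zs[1:]))


class TestLevelRegression:
    def test_exact_line(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [2 * v + 1 for v in x]
        fit = level_correlation_regression(x, y)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_independent_response_gives_near_zero_slope(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 1, 200)
        y = rng.standard_normal(200)
        fit = level_correlation_regression(x, y)
        assert abs(fit.slope) < 2.5 * fit.stderr + 0.5

    def test_degenerate_x_raises(self):
        with pytest.raises(ValueError):
            level_correlation_regression([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_level_coupled_generator_gives_positive_slope(self):
        # data generated with correlation increasing in level: slope > 0 in
        # the vast majority of seeded runs
        from markdiv.synthetic_data import SimulationConfig, generate_expression
        from markdiv.expression_divergence import fisher_transform as ft

        positive = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = SimulationConfig(
                n_pairs={"both": 80, "mixed": 80, "none": 80},
                n_background_genes=10, n_samples=40,
                level_rho_slope=0.25, level_sd=1.2, master_seed=1000 + seed)
            matrix, table = generate_expression(cfg)
            xs, ys = [], []
            for row in table.itertuples():
                x = matrix.profile(row.gene_a)
                y = matrix.profile(row.gene_b)
                r = float(np.corrcoef(x, y)[0, 1])
                z = ft(r)
                if math.isfinite(z):
                    xs.append(x.sum() + y.sum())
                    ys.append(z)
            if level_correlation_regression(xs, ys).slope > 0:
                positive += 1
        assert positive >= int(0.95 * n_runs)
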