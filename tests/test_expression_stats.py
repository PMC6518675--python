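import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lncflux as lx
from lncflux.expression_stats import benjamini_hochberg, round_half_up

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def bh_oracle(pvals):
    """Literal BH step-up: q_(i) = min over j>=i of p_(j) * m / j, capped."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def venn_oracle(sets):
    names = sorted(sets)
    regions = {}
    for el in set.union(*sets.values()):
        member = tuple(n for n in names if el in sets[n])
        regions[member] = regions.get(member, 0) + 1
    out = {}
    import itertools

    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            out["&".join(combo)] = regions.get(combo, 0)
    return out


class TestFilterExpressed:
    def test_strict_threshold_boundary(self, design_meta, matrix_factory):
        log2 = np.full((2, 18), np.log2(0.1))  # FPKM exactly 0.1
        m = matrix_factory(log2, design_meta)
        m.values.iloc[1, 0] = 0.2
        kept, n = lx.filter_expressed(m, threshold=0.1)
        assert n == 1 and kept.feature_ids == ["f1"]

    def test_count_matches_direct_numpy_count(self, expression):
        kept, n = lx.filter_expressed(expression, threshold=0.1)
        assert n == int((expression.values.max(axis=1) > 0.1).sum())

    def test_empty_matrix_rejected(self, design_meta):
        m = pd.DataFrame(np.empty((0, 18)), columns=design_meta.index)
        with pytest.raises(ValueError):
            lx.filter_expressed(lx.ExpressionMatrix(m, design_meta), 0.1)


class TestDifferentialExpression:
    def test_identical_groups_not_de(self, design_meta, matrix_factory):
        log2 = np.tile(np.arange(5)[:, None], (1, 18)).astype(float)
        res = lx.differential_expression(matrix_factory(log2, design_meta), "liver")
        for r in res:
            assert r.p_value == 1.0
            assert r.log2fc == pytest.approx(0.0, abs=1e-9)
            assert not r.is_de

    def test_feature_and_sample_order_invariance(self, expression):
        res = {r.feature_id: r for r in lx.differential_expression(expression, "liver")}
        rng = np.random.default_rng(3)
        forder = rng.permutation(expression.feature_ids)
        sorder = rng.permutation(expression.sample_ids)
        shuffled = lx.ExpressionMatrix(
            expression.values.loc[forder, sorder], expression.sample_meta.loc[sorder]
        )
        res2 = {r.feature_id: r for r in lx.differential_expression(shuffled, "liver")}
        for fid in res:
            assert res[fid].p_value == pytest.approx(res2[fid].p_value, rel=1e-12)
            assert res[fid].is_de == res2[fid].is_de

    def test_missing_group_rejected(self, design_meta, matrix_factory):
        m = matrix_factory(np.ones((3, 18)), design_meta)
        with pytest.raises(ValueError):
            lx.differential_expression(m, "kidney")

    def test_planted_effects_recovered(self, sim_config, annotation_truth, expression):
        _, truth = annotation_truth
        res = lx.differential_expression(expression, "liver")
        called = {r.feature_id for r in res if r.is_de}
        planted = set(truth.de_features["liver"])
        sensitivity = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.1


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_stepup_oracle(self, pvals):
        assert np.allclose(
            benjamini_hochberg(pvals), bh_oracle(pvals), rtol=1e-10, atol=1e-12
        )


class TestPercentDe:
    @pytest.mark.parametrize(
        "n_de,n_expr,expected",
        [
            (1930, 13815, 13.97),
            (1045, 15829, 6.60),
            (891, 18839, 4.73),
            (302, 1570, 19.24),
            (52, 1662, 3.13),
            (41, 1689, 2.43),
            (0, 100, 0.00),
        ],
    )
    def test_published_percentages(self, n_de, n_expr, expected):
        assert lx.percent_de(n_de, n_expr) == expected

    def test_rounding_is_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.115, 2) == 0.12

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            lx.percent_de(0, 0)


class TestVennCounts:
    def test_two_set_example(self):
        counts = lx.de_overlap_counts({"A": {1, 2}, "B": {2, 3}})
        assert counts == {"A": 1, "B": 1, "A&B": 1}

    def test_identical_sets_all_in_full_intersection(self):
        counts = lx.de_overlap_counts({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        assert counts["A&B&C"] == 2
        assert sum(counts.values()) == 2

    def test_matches_membership_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sets = {
                name: set(rng.choice(50, size=rng.integers(0, 30), replace=False))
                for name in ("liver", "aa", "sa")
            }
            if not any(sets.values()):
                continue
            counts = lx.de_overlap_counts(sets)
            assert counts == venn_oracle(sets)
            assert sum(counts.values()) == len(set.union(*sets.values()))


class TestCorrelationOverview:
    def test_duplicated_sample_correlates_perfectly(self, design_meta, matrix_factory):
        rng = np.random.default_rng(0)
        log2 = np.tile(rng.normal(3, 1, (50, 1)), (1, 18))
        log2 += rng.normal(0, 0.5, (50, 18))
        log2[:, 1] = log2[:, 0]
        m = matrix_factory(log2, design_meta)
        corr, _ = lx.correlation_overview(m)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pearson_on_toy_matrix(self, design_meta, matrix_factory):
        rng = np.random.default_rng(2)
        log2 = rng.normal(3, 1, (4, 18))
        m = matrix_factory(log2, design_meta)
        corr, _ = lx.correlation_overview(m)
        # explicit-sums Pearson between samples 0 and 1
        x, y = np.log2(m.values.iloc[:, 0] + 1), np.log2(m.values.iloc[:, 1] + 1)
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y**2).sum() - y.sum() ** 2
        )
        assert corr.iloc[0, 1] == pytest.approx(num / den, rel=1e-12)

    def test_constant_sample_excluded_from_means(self, design_meta, matrix_factory, caplog):
        rng = np.random.default_rng(4)
        log2 = rng.normal(3, 1, (30, 18))
        log2[:, 0] = 0.0  # constant FPKM 1 -> log2 constant
        m = matrix_factory(log2, design_meta)
        with caplog.at_level("WARNING", logger="lncflux"):
            corr, means = lx.correlation_overview(m)
        assert np.isnan(corr.iloc[0, 2])
        assert all(np.isfinite(v) for v in means.values())


class TestPvca:
    def test_tissue_only_signal_attributes_everything_to_tissue(
        self, design_meta, matrix_factory
    ):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 5, (400, 1))
        toff = rng.normal(0, 2, (400, 3))
        log2 = base + toff[:, np.repeat([0, 1, 2], 6)]
        result = lx.pvca(matrix_factory(log2, design_meta))
        assert result.weighted_proportions["tissue"] == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_is_residual_dominated(self, design_meta, matrix_factory):
        residuals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = matrix_factory(rng.normal(4, 1, (2000, 18)), design_meta)
            residuals.append(lx.pvca(m).weighted_proportions["residual"])
        assert np.mean(residuals) >= 0.95

    def test_proportions_sum_to_one_and_lie_in_unit_interval(self, expression):
        kept, _ = lx.filter_expressed(expression)
        props = lx.pvca(kept).weighted_proportions
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= v <= 1 for v in props.values())

    def test_planted_variance_ratio_recovered(self, design_meta, matrix_factory):
        ratios = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            nf = 600
            t_eff = rng.normal(0, np.sqrt(3), (nf, 3))
            g_eff = rng.normal(0, 1, (nf, 2))
            noise = rng.normal(0, 0.3, (nf, 18))
            ti = np.repeat([0, 1, 2], 6)
            gi = np.array(([0] * 3 + [1] * 3) * 3)
            log2 = 4 + t_eff[:, ti] + g_eff[:, gi] + noise
            props = lx.pvca(
                matrix_factory(log2, design_meta), min_var_explained=0.9
            ).weighted_proportions
            ratios.append(props["tissue"] / max(props["treatment"], 1e-12))
        mean_ratio = float(np.mean(ratios))
        assert 3 * 0.75 <= mean_ratio <= 3 * 1.25

    def test_unbalanced_design_requires_means_fallback(self, design_meta, matrix_factory):
        rng = np.random.default_rng(1)
        m = matrix_factory(rng.normal(4, 1, (100, 18)), design_meta)
        unbalanced = lx.ExpressionMatrix(
            m.values.iloc[:, 1:], m.sample_meta.iloc[1:]
        )
        with pytest.raises(ValueError, match="means"):
            lx.pvca(unbalanced)
        props = lx.pvca(unbalanced, method="means").weighted_proportions
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)
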