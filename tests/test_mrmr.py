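import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degrerank import (
    ExpressionMatrix,
    MRMRConfig,
    PhenotypeLabels,
    mrmr_select,
    mrmr_select_arrays,
    redundancy_pearson,
    relevance_auc,
    relevance_chi2,
    relevance_fstat,
    rffi_rank,
)
from degrerank.simulate import SyntheticConfig, simulate_expression

from .oracles import (
    auc_by_pair_counting,
    chi2_by_contingency,
    fstat_by_anova,
    stepwise_mrmr,
)


class TestRelevanceAUC:
    def test_perfect_separation(self):
        assert relevance_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_constant_feature_uninformative(self):
        assert relevance_auc([3, 3, 3, 3], [0, 0, 1, 1]) == 0.5

    def test_concordant_pair_value(self):
        # positives at values 3 and 5 vs negatives 1, 2, 4: 5 of 6 pairs
        assert relevance_auc([1, 2, 3, 4, 5], [0, 0, 1, 0, 1]) == pytest.approx(5 / 6)

    def test_folding_handles_down_regulation(self):
        x = [5, 4, 1, 0]
        assert relevance_auc(x, [0, 0, 1, 1]) == 1.0
        assert relevance_auc(x, [0, 0, 1, 1], fold=False) == 0.0

    def test_matches_pair_counting_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.standard_normal(15)
            y = rng.integers(0, 2, 15)
            if y.sum() in (0, 15):
                continue
            assert relevance_auc(x, y) == pytest.approx(
                auc_by_pair_counting(x, y), abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = np.array([0, 1] * 6)
        transformed = np.exp(2.0 * x) + 7
        assert relevance_auc(x, y) == pytest.approx(
            relevance_auc(transformed, y), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            relevance_auc([1, 2, 3], [1, 1, 1])


class TestRelevanceChi2:
    def test_constant_feature_zero(self):
        assert relevance_chi2([2, 2, 2, 2], [0, 0, 1, 1]) == 0.0

    def test_indicator_feature_matches_hand_computation(self):
        # x = c for positives, 0 otherwise: 2-cell contingency by hand
        x = np.array([0.0, 0.0, 0.0, 3.0, 3.0])
        y = np.array([0, 0, 0, 1, 1])
        total, f1 = 6.0, 2 / 5
        exp1, exp0 = total * f1, total * (1 - f1)
        by_hand = (6.0 - exp1) ** 2 / exp1 + (0.0 - exp0) ** 2 / exp0
        assert relevance_chi2(x, y) == pytest.approx(by_hand, rel=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20)
        y = rng.integers(0, 2, 20)
        y[0], y[1] = 0, 1
        assert relevance_chi2(x, y) == pytest.approx(
            relevance_chi2(x + 7, y), rel=1e-10
        )

    def test_matches_contingency_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.standard_normal(12)
            y = np.array([0] * 7 + [1] * 5)
            assert relevance_chi2(x, y) == pytest.approx(
                chi2_by_contingency(x, y), rel=1e-10
            )


class TestRelevanceFStat:
    def test_symmetric_groups_zero(self):
        assert relevance_fstat([-1, 1, -1, 1], [0, 0, 1, 1]) == 0.0

    def test_equals_pooled_t_squared(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(14)
        y = np.array([0] * 8 + [1] * 6)
        g1, g0 = x[y == 1], x[y == 0]
        n1, n0 = len(g1), len(g0)
        sp2 = ((n1 - 1) * g1.var(ddof=1) + (n0 - 1) * g0.var(ddof=1)) / (n1 + n0 - 2)
        t = (g1.mean() - g0.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
        assert relevance_fstat(x, y) == pytest.approx(t ** 2, rel=1e-10)

    def test_degenerate_constant_within_groups_capped(self):
        assert relevance_fstat([1, 1, 2, 2], [0, 0, 1, 1]) == 1e12

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(10)
        y = np.array([0] * 5 + [1] * 5)
        assert relevance_fstat(x, y) == pytest.approx(fstat_by_anova(x, y), rel=1e-10)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            relevance_fstat([1, 2, 3], [1, 0, 0])


class TestRedundancy:
    def test_perfect_linear_dependence(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert redundancy_pearson(x, 3 * x + 5) == pytest.approx(1.0)

    def test_anticorrelation_folded(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert redundancy_pearson(x, -x) == pytest.approx(1.0)

    def test_gram_schmidt_orthogonal_near_zero(self):
        rng = np.random.default_rng(123)
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        ac = a - a.mean()
        bc = b - b.mean()
        b_orth = bc - (bc @ ac) / (ac @ ac) * ac
        assert redundancy_pearson(a, b_orth + b_orth.mean()) < 0.01

    def test_constant_vector_zero(self):
        assert redundancy_pearson([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            redundancy_pearson([1, 2], [1, 2, 3])


def _planted_matrix(seed=0, n=40, p=8):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, n // 3, replace=False)] = 1
    return X, y


class TestMRMRSelect:
    def test_k1_reduces_to_argmax_relevance(self):
        X, y = _planted_matrix(3)
        trace = mrmr_select_arrays(X, y, MRMRConfig(k=1))
        rels = [relevance_auc(X[:, j], y) for j in range(X.shape[1])]
        assert trace.gene_ids[0] == str(int(np.argmax(rels)))
        assert trace.redundancy_penalty[0] == 0.0

    def test_redundant_copy_loses_to_weaker_independent_gene(self):
        """Candidates {A, A', B}: A' duplicates A (redundancy 1), so the
        weaker-but-independent B is picked second (0.8 - 0 > 0.9 - 1)."""
        rng = np.random.default_rng(0)
        n = 40
        y = np.array([0, 1] * (n // 2))
        # A: strong marker; A': exact copy; B: weaker independent marker
        a = y * 2.2 + rng.standard_normal(n) * 0.6
        b_raw = rng.standard_normal(n)
        b = y * 1.2 + b_raw
        X = np.column_stack([a, a.copy(), b])
        rels = [relevance_auc(X[:, j], y) for j in range(3)]
        assert rels[0] > rels[2] > 0.6  # A genuinely stronger than B
        trace = mrmr_select_arrays(X, y, MRMRConfig(k=2),
                                   feature_names=["A", "Acopy", "B"])
        assert trace.gene_ids == ("A", "B")

    @pytest.mark.parametrize("relevance", ["auc", "chi2", "fstat"])
    @pytest.mark.parametrize("norm", ["squared_cardinality", "cardinality"])
    def test_matches_stepwise_oracle(self, relevance, norm):
        for seed in range(5):
            X, y = _planted_matrix(seed)
            cfg = MRMRConfig(k=5, relevance=relevance, redundancy_norm=norm)
            trace = mrmr_select_arrays(X, y, cfg)
            expected = stepwise_mrmr(X, y, 5, relevance, cfg.divisor_exponent)
            assert [int(g) for g in trace.gene_ids] == expected

    def test_duplicate_of_selected_never_changes_selection(self):
        X, y = _planted_matrix(7)
        cfg = MRMRConfig(k=4)
        base = mrmr_select_arrays(X, y, cfg).gene_ids
        X_dup = np.column_stack([X, X[:, int(base[0])]])
        names = [str(i) for i in range(X.shape[1])] + ["copy"]
        dup = mrmr_select_arrays(X_dup, y, cfg, feature_names=names).gene_ids
        assert dup == base

    def test_zero_redundancy_reduces_to_top_k_relevance(self):
        rng = np.random.default_rng(21)
        n, p = 200, 6
        y = np.array([0, 1] * (n // 2))
        raw = rng.standard_normal((n, p)) + y[:, None] * np.linspace(0.1, 0.9, p)
        # orthogonalizing the centered columns makes every pairwise sample
        # correlation exactly zero, so the redundancy penalty vanishes
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))
        trace = mrmr_select_arrays(X, y, MRMRConfig(k=3))
        rels = [relevance_auc(X[:, j], y) for j in range(p)]
        top3 = set(np.argsort(rels)[::-1][:3])
        assert {int(g) for g in trace.gene_ids} == top3

    def test_deterministic(self):
        X, y = _planted_matrix(9)
        cfg = MRMRConfig(k=4, relevance="fstat")
        t1 = mrmr_select_arrays(X, y, cfg)
        t2 = mrmr_select_arrays(X, y, cfg)
        assert t1 == t2

    def test_k_exceeding_candidates_rejected(self):
        X, y = _planted_matrix(1)
        with pytest.raises(ValueError, match="exceeds"):
            mrmr_select_arrays(X, y, MRMRConfig(k=99))

    def test_expression_matrix_interface(self, tiny_matrix, tiny_labels):
        trace = mrmr_select(tiny_matrix, tiny_labels, MRMRConfig(k=2))
        assert len(trace) == 2
        assert set(trace.gene_ids) <= set(tiny_matrix.gene_ids)


class TestRFFI:
    def _data(self, seed):
        cfg = SyntheticConfig(
            n_samples=120, n_positive=40, n_genes=60, n_blocks=1, block_size=1,
            effect_size=3.0, within_block_correlation=0.0, seed=seed,
        )
        return simulate_expression(cfg)

    def test_returns_k_unique_genes(self):
        m, y, _ = self._data(0)
        genes = rffi_rank(m, y, k=5, seed=0)
        assert len(genes) == 5 and len(set(genes)) == 5

    def test_same_seed_same_ranking(self):
        m, y, _ = self._data(1)
        assert rffi_rank(m, y, k=10, seed=3) == rffi_rank(m, y, k=10, seed=3)

    def test_recovers_planted_gene(self):
        """A single 3-sigma marker among independent noise genes should
        top the importance ranking in nearly every replicate."""
        hits = 0
        for seed in range(10):
            m, y, truth = self._data(seed)
            planted = truth.loc[truth["causal"], "gene_id"].iloc[0]
            hits += rffi_rank(m, y, k=1, seed=seed)[0] == planted
        assert hits >= 9

    def test_k_exceeding_genes_rejected(self):
        m, y, _ = self._data(2)
        with pytest.raises(ValueError, match="exceeds"):
            rffi_rank(m, y, k=m.n_genes + 1)
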