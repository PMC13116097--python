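"""MARCOS compromise-utility ranking and its normalization variants."""

import numpy as np
import pytest

from healthrank import (
    CriterionSpec,
    DecisionMatrix,
    compute_weights,
    marcos_rank,
)
from healthrank.marcos import extend_with_references, marcos_normalize

from conftest import PUBLISHED_MARCOS
from oracles import marcos_oracle


def _benefit_matrix(values):
    n = len(values[0])
    specs = [CriterionSpec(f"C{j+1}", "benefit") for j in range(n)]
    labels = [f"A{i}" for i in range(len(values))]
    return DecisionMatrix(labels, specs, values)


class TestReferences:
    def test_oecd_reference_rows(self, oecd):
        ext = extend_with_references(oecd)
        assert ext.shape == (29, 6)
        ai, aai = ext[-2], ext[-1]
        assert ai[0] == 84.1 and aai[0] == 74.5  # benefit: max / min
        assert ai[5] == 1.1 and aai[5] == 38.2  # cost: min / max
        np.testing.assert_array_equal(ext[:-2], oecd.values)

    def test_single_benefit_column_ordering(self):
        m = _benefit_matrix([[1, 1], [2, 5], [3, 2]])
        ext = extend_with_references(m)
        assert ext[-2, 0] == 3 and ext[-1, 0] == 1


class TestNormalization:
    def test_ideal_row_normalizes_to_ones(self, oecd):
        ext = extend_with_references(oecd)
        n = marcos_normalize(ext, oecd.directions, "ideal_referenced")
        np.testing.assert_allclose(n[-2], 1.0, atol=1e-15)
        assert np.all(n > 0) and np.all(n <= 1 + 1e-15)

    def test_anti_ideal_variant_pins_anti_ideal_cost_cells(self, oecd):
        ext = extend_with_references(oecd)
        n = marcos_normalize(ext, oecd.directions, "anti_ideal_referenced")
        cost = ~oecd.directions
        np.testing.assert_allclose(n[-1, cost], 1.0, atol=1e-15)

    def test_known_ratios(self, oecd):
        ext = extend_with_references(oecd)
        n = marcos_normalize(ext, oecd.directions, "ideal_referenced")
        swiss = oecd.alternatives.index("Switzerland")
        assert n[swiss, 1] == pytest.approx(10963.43066 / 12434.43359)
        assert n[swiss, 2] == 1.0  # cost-column best

    def test_nonpositive_cost_value_rejected(self):
        specs = [CriterionSpec("C1", "benefit"), CriterionSpec("C2", "cost")]
        m = DecisionMatrix(["a", "b"], specs, [[1, 0.0], [2, 3]])
        ext = extend_with_references(m)
        with pytest.raises(ValueError, match="positive"):
            marcos_normalize(ext, m.directions)


class TestMarcosOnFixture:
    def test_reproduces_published_scores_and_ranks(self, oecd, oecd_weights):
        result, _ = marcos_rank(oecd, oecd_weights)
        for country, (score, rank) in PUBLISHED_MARCOS.items():
            assert result.score_of(country) == pytest.approx(score, abs=1e-8)
            assert result.rank_of(country) == rank

    def test_artifact_invariants(self, oecd, oecd_weights):
        _, art = marcos_rank(oecd, oecd_weights)
        assert art.S_AI == pytest.approx(1.0, abs=1e-12)  # weights sum to 1
        assert np.all(art.S > art.S_AAI) and np.all(art.S < art.S_AI)
        assert np.all(art.K_plus > 0) and np.all(art.K_plus <= 1)
        assert np.all(art.K_minus >= art.K_plus)
        np.testing.assert_allclose(art.f_plus + art.f_minus, 1.0, atol=1e-12)
        assert np.all(art.final > 0) and np.all(art.final < 1)


class TestMarcosProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_loop_oracle(self, random_matrix_factory, seed):
        m = random_matrix_factory(seed=seed, m=10, n=4)
        w = compute_weights(m)[0]
        result, _ = marcos_rank(m, w)
        expected = marcos_oracle(
            m.values.tolist(), m.directions.tolist(), w.weights.tolist()
        )
        np.testing.assert_allclose(result.scores, expected, atol=1e-12)

    def test_toy_matrix_orders_by_dominance(self):
        m = _benefit_matrix([[1, 10], [2, 20], [3, 30]])
        w = np.array([0.5, 0.5])
        standard, _ = marcos_rank(m, w)
        assert standard.ranks.tolist() == [3, 2, 1]
        mean, _ = marcos_rank(m, w, utility_variant="simple_mean")
        assert mean.ranks.tolist() == [3, 2, 1]

    def test_alternative_equal_to_ideal_has_unit_utility_degree(self):
        # row 0 holds every column best, so S_0 == S_AI
        m = _benefit_matrix([[9, 90], [3, 30], [5, 50]])
        _, art = marcos_rank(m, np.array([0.4, 0.6]))
        assert art.K_plus[0] == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("seed", range(6))
    def test_utility_variants_induce_same_ordering(
        self, random_matrix_factory, seed
    ):
        m = random_matrix_factory(seed=100 + seed)
        w = compute_weights(m)[0]
        standard, _ = marcos_rank(m, w)
        mean, _ = marcos_rank(m, w, utility_variant="simple_mean")
        np.testing.assert_array_equal(standard.ranks, mean.ranks)
        assert not np.allclose(standard.scores, mean.scores)

    def test_score_monotone_in_S(self, random_matrix_factory):
        m = random_matrix_factory(seed=21, m=15, n=5)
        w = compute_weights(m)[0]
        result, art = marcos_rank(m, w)
        order_by_S = np.argsort(art.S)
        order_by_f = np.argsort(result.scores)
        np.testing.assert_array_equal(order_by_S, order_by_f)

    def test_weak_dominance(self, random_matrix_factory):
        m = random_matrix_factory(seed=8, m=8, n=4)
        values = m.values.copy()
        values[0] = values[1]
        benefit = m.directions
        values[0, 0] = values[1, 0] + (1 if benefit[0] else -0.5)
        dm = m.replace_values(values)
        w = compute_weights(dm)[0]
        result, _ = marcos_rank(dm, w)
        assert result.scores[0] > result.scores[1]

    def test_rescaling_invariance(self, random_matrix_factory):
        m = random_matrix_factory(seed=17)
        w = compute_weights(m)[0]
        f0 = marcos_rank(m, w)[0].scores
        values = m.values.copy()
        values[:, 1] *= 40.0
        f1 = marcos_rank(m.replace_values(values), w)[0].scores
        np.testing.assert_allclose(f1, f0, atol=1e-12)

    def test_unknown_variant_rejected(self, oecd, oecd_weights):
        with pytest.raises(ValueError):
            marcos_rank(oecd, oecd_weights, utility_variant="median")
        ext = extend_with_references(oecd)
        with pytest.raises(ValueError):
            marcos_normalize(ext, oecd.directions, "vectorial")
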