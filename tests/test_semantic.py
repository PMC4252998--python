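import numpy as np
import pytest
import scipy.sparse as sp

from polsa.corpus import TermHeadingCounts
from polsa.dictionary import DictionaryTerm, MultiGramDictionary
from polsa.semantic import (
    ModelConfig,
    QueryError,
    SemanticModel,
    embed_query,
    fit,
    rank_headings,
    tfidf_weight,
)

from oracles import raw_space_cosine_ranking


def _counts(matrix, heading_ids=None):
    m = sp.csr_matrix(np.asarray(matrix))
    return TermHeadingCounts(
        counts=m,
        term_ids=list(range(m.shape[0])),
        heading_ids=heading_ids or [f"H{j:02d}" for j in range(m.shape[1])],
    )


def _dictionary(n_terms):
    terms = [
        DictionaryTerm(term_id=i, canonical=f"t{i}", variants={f"t{i}"}, source="gene_symbol")
        for i in range(n_terms)
    ]
    return MultiGramDictionary(terms=terms, surface_index={f"t{i}": i for i in range(n_terms)})


class TestTfidf:
    def test_term_in_every_column_zeroed(self):
        W, idf = tfidf_weight(_counts([[1, 2, 3], [0, 1, 0]]))
        assert idf[0] == 0
        assert W[0].toarray().sum() == 0

    def test_hand_arithmetic_single_column_term(self):
        # c=2, H=4, df=1 -> 2 ln 4
        W, idf = tfidf_weight(_counts([[0, 2, 0, 0], [1, 1, 1, 0]]))
        assert W[0, 1] == pytest.approx(2 * np.log(4), abs=1e-12)
        assert idf[0] == pytest.approx(np.log(4))
        assert W[0, 0] == 0

    def test_zero_cells_stay_zero(self):
        W, _ = tfidf_weight(_counts([[0, 3], [1, 0]]))
        assert W[0, 0] == 0 and W[1, 1] == 0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            tfidf_weight(_counts([[0, 0], [0, 0]]))


def _fit_diag(singular_values, threshold):
    """Fit on a diagonal matrix whose singular values are exactly as given."""
    W = sp.csr_matrix(np.diag(singular_values).astype(float))
    counts = _counts(np.eye(len(singular_values)))
    return fit(W, counts, np.ones(len(singular_values)), ModelConfig(energy_threshold=threshold))


class TestEnergyCutoff:
    def test_worked_example_3_2_1(self):
        # energies 9, 4, 1; cumulative fractions 9/14, 13/14, 1
        model = _fit_diag([3, 2, 1], 0.95)
        assert model.k == 3
        assert model.energy_fraction == pytest.approx(1.0)
        # at a threshold below 13/14 only two components are needed
        assert _fit_diag([3, 2, 1], 0.92).k == 2
        assert _fit_diag([3, 2, 1], 9 / 14).k == 1

    def test_threshold_one_keeps_full_rank(self):
        rng = np.random.default_rng(0)
        W = rng.random((6, 4))
        model = fit(sp.csr_matrix(W), _counts(np.ones((6, 4))), np.ones(6),
                    ModelConfig(energy_threshold=1.0))
        assert model.k == np.linalg.matrix_rank(W)

    def test_rank_one_matrix_needs_one_component(self):
        W = np.outer([1, 2, 3], [4, 5])
        model = fit(sp.csr_matrix(W.astype(float)), _counts(np.ones((3, 2))), np.ones(3),
                    ModelConfig(energy_threshold=0.5))
        assert model.k == 1

    @pytest.mark.parametrize("threshold", [0.3, 0.6, 0.95, 0.99])
    def test_k_is_minimal_for_every_fit(self, threshold):
        rng = np.random.default_rng(11)
        for _ in range(5):
            W = rng.random((8, 6))
            model = fit(sp.csr_matrix(W), _counts(np.ones((8, 6))), np.ones(8),
                        ModelConfig(energy_threshold=threshold))
            s = np.linalg.svd(W, compute_uv=False)
            energy = s**2 / (s**2).sum()
            assert np.cumsum(energy)[model.k - 1] >= threshold - 1e-9
            if model.k > 1:
                assert np.cumsum(energy)[model.k - 2] < threshold

    def test_singular_values_positive_and_non_increasing(self):
        model = _fit_diag([5, 4, 1e-18], 1.0)
        assert (model.singular_values > 0).all()
        assert (np.diff(model.singular_values) <= 0).all()


class TestQueryAndRanking:
    def _model_and_counts(self, seed=0, threshold=1.0, density=0.4, shape=(20, 10)):
        rng = np.random.default_rng(seed)
        C = (rng.random(shape) < density) * rng.integers(1, 6, size=shape)
        # guarantee a nonzero matrix with some informative rows
        C[0, 0] = 3
        counts = _counts(C)
        W, idf = tfidf_weight(counts)
        model = fit(W, counts, idf, ModelConfig(energy_threshold=threshold))
        return model, counts, W.toarray(), idf

    def test_single_surface_query_embeds_nonzero(self):
        model, counts, _, _ = self._model_and_counts()
        d = _dictionary(20)
        vec = embed_query(model, ["t0"], d)
        assert np.linalg.norm(vec.latent) > 0

    def test_unique_term_query_ranks_its_heading_first_at_full_rank(self):
        # term 0 occurs in exactly one heading
        C = np.zeros((4, 3))
        C[0, 1] = 5
        C[1] = [1, 1, 1]
        C[2] = [0, 2, 1]
        C[3] = [3, 0, 2]
        counts = _counts(C)
        W, idf = tfidf_weight(counts)
        model = fit(W, counts, idf, ModelConfig(energy_threshold=1.0))
        vec = embed_query(model, ["t0"], _dictionary(4))
        ranked = rank_headings(model, vec)
        # oracle: brute-force cosine in the raw TF-IDF space
        q = np.zeros(4)
        q[0] = idf[0]
        oracle = raw_space_cosine_ranking(W.toarray(), q, counts.heading_ids)
        assert ranked[0].heading_id == oracle[0][0] == "H01"
        assert ranked[0].cosine == pytest.approx(oracle[0][1], abs=1e-8)

    def test_two_term_query_is_sum_of_single_term_vectors(self):
        model, _, _, _ = self._model_and_counts()
        d = _dictionary(20)
        v01 = embed_query(model, ["t0", "t1"], d)
        np.testing.assert_allclose(
            v01.latent,
            embed_query(model, ["t0"], d).latent + embed_query(model, ["t1"], d).latent,
            atol=1e-12,
        )

    def test_out_of_dictionary_query_lists_near_misses(self):
        model, _, _, _ = self._model_and_counts()
        with pytest.raises(QueryError, match="out of dictionary"):
            embed_query(model, ["t00"], _dictionary(20))

    def test_multigram_query_resolves_through_matcher(self):
        model, counts, _, _ = self._model_and_counts()
        terms = [DictionaryTerm(0, "yellow virus fever", {"yellow virus fever"}, "heading", "H00")]
        terms += [
            DictionaryTerm(i, f"t{i}", {f"t{i}"}, "gene_symbol") for i in range(1, 20)
        ]
        d = MultiGramDictionary(terms=terms, surface_index={t.canonical: t.term_id for t in terms})
        vec = embed_query(model, ["the yellow virus fever outbreak"], d)
        assert np.linalg.norm(vec.latent) > 0

    def test_query_equal_to_heading_vector_has_cosine_one(self):
        model, _, _, _ = self._model_and_counts()
        ranked = rank_headings(model, model.heading_vectors[3].copy())
        assert ranked[0].heading_id == "H03"
        assert ranked[0].cosine == pytest.approx(1.0)

    def test_orthogonal_query_has_cosine_zero(self):
        C = np.array([[2.0, 0.0], [0.0, 3.0]])
        counts = _counts(C)
        W, idf = tfidf_weight(counts)
        model = fit(W, counts, idf, ModelConfig(energy_threshold=1.0))
        vec = embed_query(model, ["t0"], _dictionary(2))
        ranked = {r.heading_id: r.cosine for r in rank_headings(model, vec)}
        assert ranked["H01"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_query_vector_rejected(self):
        model, _, _, _ = self._model_and_counts()
        with pytest.raises(QueryError):
            rank_headings(model, np.zeros(model.k))

    def test_ranks_are_a_permutation_and_cosines_monotone(self):
        model, _, _, _ = self._model_and_counts(threshold=0.95)
        vec = embed_query(model, ["t0"], _dictionary(20))
        ranked = rank_headings(model, vec)
        assert sorted(r.rank for r in ranked) == list(range(1, 11))
        cosines = [r.cosine for r in ranked]
        assert all(a >= b for a, b in zip(cosines, cosines[1:]))
        assert all(-1 <= c <= 1 for c in cosines)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_matches_raw_space_oracle(self, seed):
        model, counts, W, idf = self._model_and_counts(seed=seed, threshold=1.0)
        d = _dictionary(20)
        for term in ["t0", "t3"]:
            tid = d.lookup(term)
            if idf[tid] == 0:
                continue
            vec = embed_query(model, [term], d)
            ranked = rank_headings(model, vec)
            q = np.zeros(20)
            q[tid] = idf[tid]
            oracle = raw_space_cosine_ranking(W, q, counts.heading_ids)
            assert [r.heading_id for r in ranked] == [h for h, _ in oracle]
            for r, (_, cos) in zip(ranked, oracle):
                assert r.cosine == pytest.approx(cos, abs=1e-8)

    def test_scale_invariance_of_cosines_and_ranks(self):
        model, counts, W, idf = self._model_and_counts(seed=3, threshold=0.95)
        counts2 = _counts(W * 7.5)  # scaled weighted matrix refit directly
        model2 = fit(sp.csr_matrix(W * 7.5), counts2, idf, ModelConfig(energy_threshold=0.95))
        d = _dictionary(20)
        v1, v2 = embed_query(model, ["t0"], d), embed_query(model2, ["t0"], d)
        r1, r2 = rank_headings(model, v1), rank_headings(model2, v2)
        assert [r.heading_id for r in r1] == [r.heading_id for r in r2]
        for a, b in zip(r1, r2):
            assert a.cosine == pytest.approx(b.cosine, abs=1e-9)


class TestPersistence:
    def test_archive_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        C = (rng.random((12, 6)) < 0.5) * rng.integers(1, 4, (12, 6))
        C[0, 0] = 2
        counts = _counts(C)
        W, idf = tfidf_weight(counts)
        model = fit(W, counts, idf, ModelConfig(energy_threshold=0.9))
        model.save(tmp_path / "arch")
        back = SemanticModel.load(tmp_path / "arch")
        assert back.k == model.k
        assert back.heading_ids == model.heading_ids
        assert back.config.energy_threshold == model.config.energy_threshold
        np.testing.assert_array_equal(back.heading_vectors, model.heading_vectors)
        np.testing.assert_array_equal(back.term_factors, model.term_factors)
        np.testing.assert_array_equal(back.idf, model.idf)
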