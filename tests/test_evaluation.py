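"""Out-of-sample evaluation and reference-signature comparison."""

import numpy as np
import pytest

from ddcat import evaluation as E
from ddcat.catalog import (build_catalog, normalize_rows,
                           renormalize_signatures)
from ddcat.factorization import kl_divergence, nmf_kl, nnls_exposures
from ddcat.fitness import cca_test_correlation
from ddcat.patterns import (random_categorization, standard_categorization,
                            transformation_matrix)


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        x = rng.random(10)
        assert E.cosine_similarity(x, x) == pytest.approx(1.0)

    def test_disjoint_supports_are_orthogonal(self):
        assert E.cosine_similarity([1, 1, 0, 0], [0, 0, 2, 3]) == 0.0

    def test_hand_case(self):
        assert E.cosine_similarity([1, 1, 0], [1, 0, 0]) == \
            pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            E.cosine_similarity([0, 0], [1, 0])


class TestTransformSignature:
    def test_identity_transformation(self, rng):
        s = rng.dirichlet(np.ones(4))
        assert np.allclose(E.transform_signature(s, np.eye(4)), s)

    def test_hand_two_category_case(self):
        t = np.array([[0.25, 0.75], [1.0, 0.0]])
        assert np.allclose(E.transform_signature(np.array([1.0, 0.0]), t),
                           [0.25, 0.75])

    def test_mass_preserved_by_row_stochastic_map(self, rng):
        t = rng.dirichlet(np.ones(6), size=4)
        s = rng.dirichlet(np.ones(4))
        assert E.transform_signature(s, t).sum() == pytest.approx(1.0)

    def test_empty_category_mass_renormalized_with_warning(self):
        t = np.array([[1.0, 0.0], [0.0, 0.0]])   # second category empty
        with pytest.warns(UserWarning, match="empty"):
            out = E.transform_signature(np.array([0.5, 0.5]), t)
        assert out.sum() == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            E.transform_signature(np.ones(3), np.eye(4))


class TestMatchToReference:
    def test_self_reference_matches_at_one(self, rng):
        h = rng.dirichlet(np.ones(96), size=3)
        ref = E.ReferenceSignatureSet(matrix=h.copy(),
                                      names=["s1", "s2", "s3"])
        matches = E.match_to_reference(h, np.eye(96), ref)
        for i, m in enumerate(matches):
            assert m.matches[0] == (f"s{i + 1}", pytest.approx(1.0))
            assert not m.sub_threshold

    def test_impossible_threshold_flags_best_match(self, rng):
        h = rng.dirichlet(np.ones(8), size=2)
        ref = E.ReferenceSignatureSet(matrix=h.copy(), names=["a", "b"])
        matches = E.match_to_reference(h, np.eye(8), ref, threshold=1.1)
        assert all(m.sub_threshold and len(m.matches) == 1 for m in matches)

    def test_noisy_copies_recover_one_to_one_matching(self, rng):
        ref_mat = rng.dirichlet(np.full(96, 0.1), size=3)
        ref = E.ReferenceSignatureSet(matrix=ref_mat, names=["a", "b", "c"])
        noisy = ref_mat + 0.002 * rng.random((3, 96))
        noisy /= noisy.sum(axis=1, keepdims=True)
        matches = E.match_to_reference(noisy[[2, 0, 1]], np.eye(96), ref)
        assert [m.matches[0][0] for m in matches] == ["c", "a", "b"]


class TestPrevalenceRanking:
    def test_single_signature_trivial(self, rng):
        ref = E.ReferenceSignatureSet(matrix=rng.dirichlet(np.ones(5), (1,)),
                                      names=["only"])
        counts = (10 * rng.random((4, 5))).astype(int) + 1
        assert E.prevalence_ranking(ref, counts) == ["only"]

    def test_generating_signature_ranked_first(self):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.5, 0.5])
        ref = E.ReferenceSignatureSet(matrix=np.vstack([b, a]),
                                      names=["b", "a"])
        counts = np.array([[6, 4, 0, 1], [5, 5, 1, 0]])
        assert E.prevalence_ranking(ref, counts) == ["a", "b"]

    def test_category_space_mismatch_rejected(self, rng):
        ref = E.ReferenceSignatureSet(matrix=rng.dirichlet(np.ones(5), (1,)),
                                      names=["x"])
        with pytest.raises(ValueError, match="category space"):
            E.prevalence_ranking(ref, np.ones((2, 4)))


class TestOutOfSampleEvaluation:
    @pytest.fixture(scope="class")
    def catalogs(self, fix):
        def make(cat):
            return (build_catalog(fix.wgs_sequences, cat),
                    build_catalog(fix.wes_sequences, cat))
        return make

    def test_planted_beats_random_reconstruction(self, fix, dataset, catalogs):
        reports = {}
        for name, cat in (("planted", fix.truth.planted_categorization),
                          ("random", random_categorization(0))):
            wgs, wes = catalogs(cat)
            u_wgs, u_wes = dataset.opportunity_vectors(cat)
            reports[name] = E.out_of_sample_evaluation(
                cat, wgs, wes,
                {"DDR": dataset.expression},
                [3], u_wgs, u_wes, n_restarts=3, nmf_max_iter=500,
                nmf_tol=1e-5, n_folds=5)
        assert (reports["planted"].reconstruction_error[3]
                < reports["random"].reconstruction_error[3])
        assert (reports["planted"].cca_correlation[(3, "DDR")]
                > reports["random"].cca_correlation[(3, "DDR")])

    def test_control_gene_set_scores_below_coupled(self, fix, dataset,
                                                   catalogs):
        cat = fix.truth.planted_categorization
        wgs, wes = catalogs(cat)
        u_wgs, u_wes = dataset.opportunity_vectors(cat)
        ctl = fix.cohorts.expression[fix.cohorts.gene_sets["control"]]
        report = E.out_of_sample_evaluation(
            cat, wgs, wes,
            {"DDR": dataset.expression, "control": ctl.to_numpy(float)},
            [2, 3], u_wgs, u_wes, n_restarts=3, nmf_max_iter=500,
            nmf_tol=1e-5, n_folds=5)
        assert set(report.reconstruction_error) == {2, 3}
        for k in (2, 3):
            assert (report.cca_correlation[(k, "control")]
                    < report.cca_correlation[(k, "DDR")])

    def test_standard_categorization_reduces_to_classical_workflow(
            self, fix, dataset, standard_cat, catalogs):
        """With the standard categorization (T = identity) the pipeline is
        exactly the classical 96-category NMF -> NNLS -> CCA chain."""
        t = transformation_matrix(standard_cat)
        assert np.allclose(t.matrix, np.eye(96))
        wgs, wes = catalogs(standard_cat)
        u_wgs, u_wes = dataset.opportunity_vectors(standard_cat)
        report = E.out_of_sample_evaluation(
            standard_cat, wgs, wes, {"DDR": dataset.expression}, [3],
            u_wgs, u_wes, n_restarts=3, nmf_seed=11, fold_seed=5,
            nmf_max_iter=500, nmf_tol=1e-5, n_folds=5)
        # classical chain, assembled by hand with the same seeds
        v_wgs, v_wes = normalize_rows(wgs), normalize_rows(wes)
        res = nmf_kl(v_wgs, 3, n_restarts=3, seed=11 + 3, max_iter=500,
                     tol=1e-5)
        h = renormalize_signatures(res.h, u_wgs, u_wes)
        w = nnls_exposures(v_wes, h)
        assert report.reconstruction_error[3] == pytest.approx(
            kl_divergence(v_wes, w, h))
        assert report.cca_correlation[(3, "DDR")] == pytest.approx(
            cca_test_correlation(w, dataset.expression, n_folds=5, seed=5))

    def test_reference_matching_included_when_reference_given(
            self, fix, dataset, standard_cat, catalogs, rng):
        wgs, wes = catalogs(standard_cat)
        u_wgs, u_wes = dataset.opportunity_vectors(standard_cat)
        ref = E.ReferenceSignatureSet(
            matrix=rng.dirichlet(np.ones(96), size=2), names=["r1", "r2"])
        report = E.out_of_sample_evaluation(
            standard_cat, wgs, wes, {}, [2], u_wgs, u_wes, n_restarts=2,
            nmf_max_iter=400, nmf_tol=1e-5, reference=ref)
        assert len(report.reference_matches[2]) == 2
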