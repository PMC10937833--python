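import numpy as np
import pandas as pd
import pytest

from sigplier import (
    ExpressionMatrix,
    PlierDecomposition,
    PlierModel,
    estimate_num_lvs,
    plier_loss,
    transform_plier,
)
from sigplier.data_model import LOG2_TPM_HALF


def _random_prior(rng, n_genes, n_sigs, p=0.15):
    C = (rng.random((n_genes, n_sigs)) < p).astype(float)
    return pd.DataFrame(C[:, C.sum(axis=0) >= 1])


class TestLoss:
    def test_all_zero_factors_leave_only_the_data_term(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(6, 4))
        C = np.ones((6, 2))
        val = plier_loss(Y, np.zeros((6, 3)), np.zeros((3, 4)), C, np.zeros((2, 3)), 1, 1, 1)
        assert val == pytest.approx(np.linalg.norm(Y) ** 2)

    def test_exact_factorization_gives_zero(self):
        rng = np.random.default_rng(1)
        Z = np.abs(rng.normal(size=(6, 2)))
        B = rng.normal(size=(2, 4))
        U = np.abs(rng.normal(size=(3, 2)))
        C = rng.random((6, 3))
        assert plier_loss(C @ U @ B, C @ U, B, C, U, 1.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(2)
        Y, Z, B = rng.normal(size=(2, 2)), rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        C, U = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        l1, l2, l3 = 0.7, 0.3, 1.1
        expected = 0.0
        R1, R2 = Y - Z @ B, Z - C @ U
        for i in range(2):
            for j in range(2):
                expected += R1[i, j] ** 2 + l1 * R2[i, j] ** 2
                expected += l2 * B[i, j] ** 2 + l3 * abs(U[i, j])
        assert plier_loss(Y, Z, B, C, U, l1, l2, l3) == pytest.approx(expected)

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="conformable"):
            plier_loss(np.ones((3, 2)), np.ones((3, 2)), np.ones((3, 2)),
                       np.ones((3, 1)), np.ones((1, 2)), 1, 1, 1)


class TestFit:
    def test_loss_trace_monotone_and_factors_nonnegative(self, fitted_small):
        _, _, model = fitted_small
        trace = model.loss_trace
        rel = np.diff(trace) / trace[:-1]
        assert rel.max() <= 1e-8
        assert model.Z.to_numpy().min() >= 0
        assert model.U.to_numpy().min() >= 0

    def test_huge_l1_penalty_empties_u(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(40, 60))
        est = PlierDecomposition(
            prior=_random_prior(rng, 60, 6), n_components=4,
            lambda1=1.0, lambda2=0.1, lambda3=1e6, max_outer_iter=30,
        )
        est.fit(Y)
        assert np.count_nonzero(est.signature_weights_) == 0

    def test_k_larger_than_dimensions_is_an_error(self):
        rng = np.random.default_rng(4)
        est = PlierDecomposition(prior=_random_prior(rng, 20, 4), n_components=15)
        with pytest.raises(ValueError, match="k="):
            est.fit(rng.normal(size=(10, 20)))

    def test_fit_is_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(30, 50))
        prior = _random_prior(rng, 50, 5)
        fits = [
            PlierDecomposition(prior=prior, n_components=4, random_state=11).fit(Y)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(fits[0].loadings_, fits[1].loadings_)
        np.testing.assert_array_equal(fits[0].scores_, fits[1].scores_)
        np.testing.assert_array_equal(fits[0].signature_weights_, fits[1].signature_weights_)


class TestEstimateNumLvs:
    def test_pure_noise_has_at_most_two_components(self):
        Y = np.random.default_rng(6).normal(size=(200, 50))
        assert estimate_num_lvs(Y, seed=6) <= 2

    def test_planted_rank_three_is_recovered(self):
        rng = np.random.default_rng(7)
        signal = rng.normal(size=(200, 3)) @ rng.normal(size=(3, 50)) * 3.0
        Y = signal + 0.3 * rng.normal(size=(200, 50))
        assert estimate_num_lvs(Y, seed=7) == 3

    def test_deterministic_given_seed(self):
        Y = np.random.default_rng(8).normal(size=(60, 30))
        assert estimate_num_lvs(Y, seed=1) == estimate_num_lvs(Y, seed=1)

    def test_constant_matrix_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_num_lvs(np.ones((10, 10)))


class TestTransform:
    def test_training_data_reproduces_training_scores(self, fitted_small):
        emf, _, model = fitted_small
        scores = transform_plier(model, emf)
        np.testing.assert_allclose(scores.values, model.B.to_numpy(), atol=1e-6)
        assert scores.lv_names == model.lv_names

    def test_orthonormal_loadings_reduce_to_projection(self):
        rng = np.random.default_rng(9)
        Z, _ = np.linalg.qr(rng.normal(size=(20, 4)))
        est = PlierDecomposition(standardize=False)
        est.loadings_ = Z
        est.lambda2_ = 0.0
        est.gene_means_ = np.zeros(20)
        est.gene_sds_ = np.ones(20)
        est.gene_universe_ = list(range(20))
        Ynew = rng.normal(size=(5, 20))
        np.testing.assert_allclose(est.transform(Ynew), Ynew @ Z, atol=1e-10)

    def test_missing_genes_are_zero_filled(self, fitted_small):
        emf, _, model = fitted_small
        n_drop = emf.n_genes // 10
        sub = ExpressionMatrix(
            emf.genes[n_drop:], emf.samples, emf.values[n_drop:], emf.scale
        )
        scores = transform_plier(model, sub)
        assert np.all(np.isfinite(scores.values))
        # still close to the full-data scores: only 10% of genes dropped
        full = transform_plier(model, emf)
        corr = np.corrcoef(scores.values.ravel(), full.values.ravel())[0, 1]
        assert corr > 0.95

    def test_low_overlap_is_an_error(self, fitted_small):
        emf, _, model = fitted_small
        keep = emf.n_genes // 3
        sub = ExpressionMatrix(emf.genes[:keep], emf.samples, emf.values[:keep], emf.scale)
        with pytest.raises(ValueError, match="model genes"):
            transform_plier(model, sub)

    def test_raw_scale_matrix_is_an_error(self, fitted_small):
        emf, _, model = fitted_small
        raw = ExpressionMatrix(emf.genes, emf.samples, np.abs(emf.values), "tpm")
        with pytest.raises(Exception, match="log2"):
            transform_plier(model, raw)


class TestSerialization:
    def test_directory_roundtrip_is_value_exact(self, fitted_small, tmp_path):
        emf, _, model = fitted_small
        model.save(tmp_path / "model")
        back = PlierModel.load(tmp_path / "model")
        for attr in ("Z", "B", "U", "gene_stats"):
            pd.testing.assert_frame_equal(getattr(back, attr), getattr(model, attr))
        np.testing.assert_array_equal(back.loss_trace, model.loss_trace)
        assert back.config["n_components"] == model.config["n_components"]
        # the reloaded model projects identically
        np.testing.assert_allclose(
            transform_plier(back, emf).values,
            transform_plier(model, emf).values,
        )
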