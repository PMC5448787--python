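"""Feature stacking, contribution factors and the weighted Fisher fusion."""

import numpy as np
import pytest

from palmfuse import fusion
from palmfuse.errors import InvalidArgumentError, NoDiscriminativeInformationError
from palmfuse.fusion import BIMFFeatureMatrix


def make_sample(bimfs_by_band, K, label=0):
    return fusion.build_feature_matrix(bimfs_by_band, K=K, label=label)


def constant_sample(c, label, shape=(2, 2), K=1):
    """A sample whose every BIMF is the constant c (1 level, 4 bands)."""
    bands = {b: [np.full(shape, float(c))] for b in fusion.BANDS}
    return make_sample(bands, K=K, label=label)


class TestBuildFeatureMatrix:
    def test_layout_band_major_level_minor(self, rng):
        bands = {b: [rng.random((2, 2))] for b in fusion.BANDS}
        sample = make_sample(bands, K=1)
        assert sample.V.shape == (4, 4)
        np.testing.assert_array_equal(sample.V[:, 0], bands["blue"][0].ravel())
        np.testing.assert_array_equal(sample.V[:, 2], bands["red"][0].ravel())

    def test_four_levels_give_sixteen_columns(self, rng):
        bands = {b: [rng.random((3, 3)) for _ in range(4)] for b in fusion.BANDS}
        assert make_sample(bands, K=4).V.shape == (9, 16)

    def test_unit_vector_recovers_blue_bimf(self, rng):
        bands = {b: [rng.random((3, 2))] for b in fusion.BANDS}
        sample = make_sample(bands, K=1)
        e1 = np.zeros(4)
        e1[0] = 1.0
        np.testing.assert_array_equal((sample.V @ e1).reshape(3, 2), bands["blue"][0])

    def test_missing_band_and_level_mismatch_rejected(self, rng):
        bands = {b: [rng.random((2, 2))] for b in fusion.BANDS[:3]}
        with pytest.raises(InvalidArgumentError):
            make_sample(bands, K=1)
        bands = {b: [rng.random((2, 2))] * (1 if b == "nir" else 2) for b in fusion.BANDS}
        with pytest.raises(InvalidArgumentError):
            make_sample(bands, K=2)

    def test_band_subset_selects_columns(self, rng):
        bands = {b: [rng.random((2, 2)) for _ in range(2)] for b in fusion.BANDS}
        sample = make_sample(bands, K=2)
        sub = sample.band_subset(("red", "nir"))
        np.testing.assert_array_equal(sub.V, sample.V[:, [4, 5, 6, 7]])


class TestContributionFactors:
    def test_all_same_class_neighbors_give_zero(self):
        # two tight clusters far apart: every sample's k neighbors share its class
        samples = [constant_sample(c, label=0) for c in (0.0, 0.1, 0.2)]
        samples += [constant_sample(c, label=1) for c in (100.0, 100.1, 100.2)]
        cw = fusion.contribution_factors(samples, k=2, delta=5.0)
        np.testing.assert_array_equal(cw.mu, 0.0)

    def test_all_other_class_neighbors_give_one(self):
        # one isolated class-0 sample among class-1 samples
        samples = [constant_sample(0.0, label=0),
                   constant_sample(0.1, label=1),
                   constant_sample(-0.1, label=1),
                   constant_sample(50.0, label=1)]
        cw = fusion.contribution_factors(samples, k=2, delta=5.0)
        assert cw.mu[0] == 1.0

    def test_equidistant_mixed_neighbors_give_half(self):
        samples = [constant_sample(0.0, label=0),
                   constant_sample(1.0, label=0),
                   constant_sample(-1.0, label=1),
                   constant_sample(80.0, label=1)]
        cw = fusion.contribution_factors(samples, k=2, delta=5.0)
        assert cw.mu[0] == pytest.approx(0.5)

    def test_mu_bounded_in_unit_interval(self, rng):
        samples = [constant_sample(rng.normal(), label=int(i % 3)) for i in range(12)]
        cw = fusion.contribution_factors(samples, k=4, delta=5.0)
        assert np.all(cw.mu >= 0.0) and np.all(cw.mu <= 1.0)

    def test_k_must_be_less_than_n(self):
        samples = [constant_sample(i, label=i % 2) for i in range(3)]
        with pytest.raises(InvalidArgumentError):
            fusion.contribution_factors(samples, k=3)


def random_samples(rng, n=12, n_classes=3, shape=(3, 3), K=2):
    out = []
    for i in range(n):
        bands = {b: [rng.normal(size=shape) for _ in range(K)] for b in fusion.BANDS}
        out.append(make_sample(bands, K=K, label=int(i % n_classes)))
    return out


class TestScatterMatrices:
    def test_naive_loop_oracle_on_scalar_images(self, rng):
        # 1x1 images: V rows are single 4-vectors; compare to direct arithmetic
        samples = [constant_sample(v, label=l, shape=(1, 1))
                   for v, l in [(1.0, 0), (2.0, 0), (5.0, 1)]]
        mu = np.array([0.5, 1.0, 0.25])
        D, Dw = fusion.scatter_matrices(samples, mu)
        rows = np.array([[1.0] * 4, [2.0] * 4, [5.0] * 4])
        vbar = rows.mean(axis=0)
        D_exp = sum(m * np.outer(r - vbar, r - vbar) for m, r in zip(mu, rows))
        cbar0 = rows[:2].mean(axis=0)
        Dw_exp = (mu[0] * np.outer(rows[0] - cbar0, rows[0] - cbar0)
                  + mu[1] * np.outer(rows[1] - cbar0, rows[1] - cbar0))
        np.testing.assert_allclose(D, D_exp)
        np.testing.assert_allclose(Dw, Dw_exp, atol=1e-12)

    def test_zero_weights_give_zero_matrices(self, rng):
        samples = random_samples(rng, n=6)
        D, Dw = fusion.scatter_matrices(samples, np.zeros(6))
        assert not np.any(D) and not np.any(Dw)

    def test_uniform_weights_reduce_to_classic_fisher(self, rng):
        samples = random_samples(rng)
        D1, Dw1 = fusion.scatter_matrices(samples, np.ones(len(samples)))
        D0, Dw0 = fusion.scatter_matrices(samples, None)
        np.testing.assert_allclose(D1, D0)
        np.testing.assert_allclose(Dw1, Dw0)

    def test_symmetric_positive_semidefinite(self, rng):
        samples = random_samples(rng)
        mu = rng.random(len(samples))
        D, Dw = fusion.scatter_matrices(samples, mu)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(Dw, Dw.T)
        assert np.linalg.eigvalsh(D).min() >= -1e-8
        assert np.linalg.eigvalsh(Dw).min() >= -1e-8

    def test_single_class_rejected(self, rng):
        samples = [constant_sample(i, label=0) for i in range(3)]
        with pytest.raises(InvalidArgumentError):
            fusion.scatter_matrices(samples)


class TestSolveFusionCoefficients:
    def test_identity_within_scatter_reduces_to_eigenproblem(self, rng):
        r = rng.normal(size=(6, 6))
        D = r @ r.T
        model = fusion.solve_fusion_coefficients(D, np.eye(6), ridge=0.0)
        w, v = np.linalg.eigh(D)
        lead = v[:, -1]
        assert abs(abs(model.phi @ lead)) == pytest.approx(1.0, abs=1e-10)
        assert model.eigenvalue == pytest.approx(w[-1])

    def test_diagonal_closed_form(self):
        model = fusion.solve_fusion_coefficients(np.diag([4.0, 1.0]), np.eye(2), ridge=0.0)
        np.testing.assert_allclose(model.phi, [1.0, 0.0], atol=1e-12)
        assert model.eigenvalue == pytest.approx(4.0)

    def test_generalized_eigenpair_residual(self, rng):
        for _ in range(10):
            r1 = rng.normal(size=(8, 8))
            r2 = rng.normal(size=(8, 8))
            D = r1 @ r1.T
            Dw = r2 @ r2.T + np.eye(8)
            model = fusion.solve_fusion_coefficients(D, Dw)
            resid = D @ model.phi - model.eigenvalue * (Dw + model.ridge * np.eye(8)) @ model.phi
            assert np.linalg.norm(resid) <= 1e-8 * max(1.0, np.linalg.norm(D))

    def test_sign_fixed_largest_entry_positive(self, rng):
        r = rng.normal(size=(5, 5))
        model = fusion.solve_fusion_coefficients(r @ r.T, np.eye(5))
        assert model.phi[np.argmax(np.abs(model.phi))] > 0

    def test_zero_between_class_scatter_rejected(self):
        with pytest.raises(NoDiscriminativeInformationError):
            fusion.solve_fusion_coefficients(np.zeros((4, 4)), np.eye(4))


class TestFuse:
    def test_unit_vector_selects_blue_bimf(self, rng):
        bands = {b: [rng.random((2, 3))] for b in fusion.BANDS}
        sample = make_sample(bands, K=1)
        model = fusion.FusionModel(phi=np.eye(4)[0], K=1)
        fused = fusion.fuse(sample, model, rescale=False)
        np.testing.assert_allclose(fused.F, bands["blue"][0])

    def test_all_ones_equals_sum_rule(self, rng):
        sample = random_samples(rng, n=1)[0]
        model = fusion.FusionModel(phi=np.ones(8), K=2)
        np.testing.assert_array_equal(fusion.fuse(sample, model).F,
                                      fusion.sum_rule_baseline(sample).F)

    def test_linear_before_rescale(self, rng):
        sample = random_samples(rng, n=1)[0]
        phi = rng.normal(size=8)
        f1 = fusion.fuse(sample, fusion.FusionModel(phi=phi, K=2), rescale=False).F
        f2 = fusion.fuse(sample, fusion.FusionModel(phi=3.0 * phi, K=2), rescale=False).F
        np.testing.assert_allclose(f2, 3.0 * f1)

    def test_rescaled_output_in_unit_interval(self, rng):
        sample = random_samples(rng, n=1)[0]
        f = fusion.fuse(sample, fusion.FusionModel(phi=rng.normal(size=8), K=2)).F
        assert f.min() == 0.0 and f.max() == 1.0

    def test_shape_mismatch_rejected(self, rng):
        sample = random_samples(rng, n=1)[0]
        with pytest.raises(InvalidArgumentError):
            fusion.fuse(sample, fusion.FusionModel(phi=np.ones(5), K=1))

    def test_sum_rule_duplicated_band_prerescale(self, rng):
        img = rng.random((2, 2))
        bands = {b: [img] for b in fusion.BANDS}
        sample = make_sample(bands, K=1)
        fused = fusion.sum_rule_baseline(sample, rescale=False)
        np.testing.assert_allclose(fused.F, 4.0 * img)


class TestCriterionReduction:
    def test_uniform_mu_matches_classic_direction(self, rng):
        for _ in range(20):
            samples = random_samples(rng, n=10, n_classes=3, shape=(2, 2), K=1)
            D, Dw = fusion.scatter_matrices(samples, 0.7 * np.ones(10))
            weighted = fusion.solve_fusion_coefficients(D, Dw)
            classic = fusion.classic_fisher_baseline(samples)
            cosine = abs(weighted.phi @ classic.phi)
            assert cosine > 0.9999

    def test_model_json_roundtrip(self, rng):
        samples = random_samples(rng)
        model = fusion.fit_weighted_fisher(samples, k=3, delta=5.0)
        restored = fusion.FusionModel.from_json(model.to_json())
        np.testing.assert_allclose(restored.phi, model.phi)
        assert restored.hyperparams == model.hyperparams
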