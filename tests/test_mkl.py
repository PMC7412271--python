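import numpy as np
import pytest

import mklselect as m
from mklselect.exceptions import (
    DegenerateModelError,
    LabelError,
    StructuralError,
)
from mklselect.mkl import MKLResults, combine_kernels, compute_wm_norms, update_eta

from conftest import fit_default


class TestKernelAlgebra:
    def test_one_hot_weights_select_single_gram(self):
        rng = np.random.default_rng(0)
        grams = [rng.random((4, 4)) for _ in range(3)]
        np.testing.assert_array_equal(
            combine_kernels(grams, [0, 1, 0]), grams[1]
        )

    def test_convex_combination_of_identical_grams(self):
        g = np.random.default_rng(1).random((3, 3))
        np.testing.assert_allclose(combine_kernels([g, g], [0.5, 0.5]), g)

    def test_hand_arithmetic(self):
        g1 = np.eye(2)
        g2 = np.ones((2, 2))
        np.testing.assert_allclose(
            combine_kernels([g1, g2], [0.25, 0.75]), [[1, 0.75], [0.75, 1]]
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(StructuralError):
            combine_kernels([np.eye(2), np.eye(3)], [0.5, 0.5])

    def test_wm_norms_scaling_and_hand_expansion(self):
        grams = [np.eye(2)]
        y = np.array([1.0, -1.0])
        # eta zero -> zero; alpha zero -> zero
        assert compute_wm_norms([0.0], [1, 1], y, grams)[0] == 0.0
        assert compute_wm_norms([1.0], [0, 0], y, grams)[0] == 0.0
        # N=2, y=(+1,-1), alpha=(1,1), K=I, eta=1 -> ||w||^2 = 2
        np.testing.assert_allclose(compute_wm_norms([1.0], [1, 1], y, grams), [2.0])


class TestEtaUpdate:
    def test_equal_norms_give_uniform_simplex_weights(self):
        np.testing.assert_allclose(update_eta([2.0] * 4, p=1), [0.25] * 4)

    def test_l1_closed_form(self):
        # ||w||_2 = (3, 1): eta = (0.75, 0.25)
        np.testing.assert_allclose(update_eta([9.0, 1.0], p=1), [0.75, 0.25])

    @pytest.mark.parametrize("p", [1.0, 2.0, 3.0])
    def test_lp_normalization_identity(self, p):
        rng = np.random.default_rng(2)
        eta = update_eta(rng.random(5) + 0.1, p=p)
        np.testing.assert_allclose(np.sum(eta ** p), 1.0, atol=1e-10)
        assert np.all(eta >= 0)

    def test_zero_norm_source_gets_zero_weight(self):
        eta = update_eta([4.0, 0.0], p=1)
        np.testing.assert_allclose(eta, [1.0, 0.0])

    def test_all_zero_norms_raise(self):
        with pytest.raises(DegenerateModelError):
            update_eta([0.0, 0.0], p=1)


class TestTraining:
    def test_single_source_weight_is_one(self, two_source_ds):
        ds = two_source_ds.select_sources(["informative"])
        res = fit_default(ds)
        np.testing.assert_allclose(res.eta, [1.0])

    def test_informative_source_outweighs_noise(self, two_source_ds):
        res = fit_default(two_source_ds, p=1.0)
        assert res.eta[0] > res.eta[1]

    def test_training_is_deterministic(self, two_source_ds):
        a = fit_default(two_source_ds)
        b = fit_default(two_source_ds)
        np.testing.assert_array_equal(a.eta, b.eta)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        assert a.bias == b.bias

    @pytest.mark.parametrize("p", [1.0, 2.0])
    def test_eta_on_unit_lp_ball_after_every_update(self, two_source_ds, p):
        res = fit_default(two_source_ds, p=p)
        norms = np.sum(np.abs(res.eta_history) ** p, axis=1) ** (1.0 / p)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)
        assert np.all(res.eta_history >= 0)

    def test_dual_feasibility_at_convergence(self, two_source_ds):
        cfg_C, cfg_tau = 2.0, 1e-4
        res = fit_default(two_source_ds, C=cfg_C, tau=cfg_tau)
        assert np.all(res.alpha >= -1e-12) and np.all(res.alpha <= cfg_C + 1e-12)
        assert abs(np.dot(res.alpha, res.labels)) <= 10 * cfg_tau

    def test_single_class_labels_rejected(self):
        x = np.arange(10, dtype=float).reshape(-1, 1)
        with pytest.raises(LabelError):
            ds = m.MultiSourceDataset([x], ["a"], np.ones(10, dtype=int))

    def test_k_too_large_rejected(self, two_source_ds):
        with pytest.raises(Exception, match="K"):
            m.MKLSourceSelection(two_source_ds, m.MKLConfig(K=60))


class TestPrediction:
    def test_separable_fit_classifies_its_support_vectors(self, two_source_ds):
        res = fit_default(two_source_ds, C=10.0)
        pred = res.predict(two_source_ds)
        sv = res.sv_indices
        frac = np.mean(pred[sv] == two_source_ds.labels[sv])
        assert frac == 1.0

    def test_zero_alpha_scores_equal_bias_and_tie_goes_positive(self, two_source_ds):
        res = fit_default(two_source_ds)
        res.stored_alpha = np.zeros_like(res.stored_alpha)
        res.bias = 0.0
        f = res.decision_function(two_source_ds)
        np.testing.assert_array_equal(f, 0.0)
        assert np.all(res.predict(two_source_ds) == 1)

    def test_permuting_test_order_permutes_predictions(self, two_source_ds):
        res = fit_default(two_source_ds)
        perm = np.random.default_rng(5).permutation(two_source_ds.n_samples)
        p1 = res.predict(two_source_ds)
        p2 = res.predict(two_source_ds.subset(perm))
        np.testing.assert_array_equal(p1[perm], p2)

    def test_source_mismatch_raises(self, two_source_ds):
        res = fit_default(two_source_ds)
        flipped = two_source_ds.select_sources(["noise", "informative"])
        with pytest.raises(StructuralError):
            res.decision_function(flipped)

    def test_test_accuracy_high_on_well_separated_fixture(self):
        spec = m.recovery_spec(n_samples=200, delta=4.0, seed=3)
        ds = m.make_multisource(spec)
        tr, te = m.split_dataset(ds, m.SplitSpec(seed=3))
        tr, (te,) = m.standardize(tr, [te])
        res = m.MKLSourceSelection(tr, m.MKLConfig(p=1, K=7)).fit()
        assert res.score_report(te).accuracy > 90.0


def _overlapping_all_sv_dataset():
    """Heavily overlapping classes + small C: every training sample ends up
    at the box bound, i.e. all samples are support vectors."""
    rng = np.random.default_rng(9)
    n = 40
    y = np.array([1, -1] * (n // 2))
    a = rng.normal(0, 1, (n, 2)) + np.where(y > 0, 0.1, -0.1)[:, None]
    b = rng.normal(0, 1, (n, 2))
    return m.MultiSourceDataset([a, b], ["a", "b"], y)


class TestAlgorithmReductions:
    def test_alg2_and_alg3_coincide_when_all_samples_are_svs(self):
        ds = _overlapping_all_sv_dataset()
        res2 = fit_default(ds, C=0.05, algorithm_id=2)
        assert res2.sv_indices.size == ds.n_samples  # premise of the property
        res3 = fit_default(ds, C=0.05, algorithm_id=3)
        test = m.make_multisource(
            m.SynthSpec(
                n_samples=20,
                sources=[
                    m.SourceSpec("a", 2, "noise"),
                    m.SourceSpec("b", 2, "noise"),
                ],
                seed=11,
            )
        )
        np.testing.assert_allclose(
            res2.decision_function(test), res3.decision_function(test)
        )
        np.testing.assert_array_equal(res2.predict(test), res3.predict(test))


class TestSerialization:
    def test_roundtrip_reproduces_predictions(self, tmp_path, two_source_ds):
        for alg in (1, 2, 3):
            res = fit_default(two_source_ds, algorithm_id=alg)
            path = tmp_path / f"model{alg}.npz"
            res.save(path)
            back = MKLResults.load(path)
            np.testing.assert_array_equal(
                res.predict(two_source_ds), back.predict(two_source_ds)
            )
            np.testing.assert_allclose(
                res.decision_function(two_source_ds),
                back.decision_function(two_source_ds),
            )
            np.testing.assert_array_equal(res.eta, back.eta)

    def test_summary_mentions_sources_and_weights(self, two_source_ds):
        res = fit_default(two_source_ds)
        text = res.summary()
        assert "informative" in text and "eta" in text
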