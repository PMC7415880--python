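"""Model objectives, training behavior and inference outputs."""

import numpy as np
import pandas as pd
import pytest

import citevae as cv
from citevae.model import SemiSupervisedVAE


@pytest.fixture
def tiny_batch():
    # matches the tiny_untrained architecture: 10 genes, 3 proteins
    rng = np.random.default_rng(0)
    counts = rng.poisson(3, (3, 10)).astype(float)
    labels = rng.random((3, 3))
    return counts, labels


class TestEncodeDecode:
    def test_identical_cells_identical_posteriors(self, trained_model, small_dataset):
        x = small_dataset["counts"].values[:1]
        code = trained_model.encode(np.vstack([x, x]))
        np.testing.assert_array_equal(code.mean[0], code.mean[1])
        np.testing.assert_array_equal(code.stddev[0], code.stddev[1])

    def test_posterior_stddev_positive(self, trained_model, small_dataset):
        code = trained_model.encode(small_dataset["counts"].values)
        assert (code.stddev > 0).all()

    def test_untrained_state_finite(self, tiny_untrained):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.poisson(5, (10, 10))
            code = tiny_untrained.encode(x)
            assert np.isfinite(code.mean).all() and np.isfinite(code.stddev).all()
            assert np.isfinite(tiny_untrained.impute(x)).all()

    def test_gene_dimension_mismatch(self, tiny_untrained):
        with pytest.raises(ValueError, match="gene dimension"):
            tiny_untrained.encode(np.zeros((2, 99)))

    def test_decode_valid_ranges(self, tiny_untrained):
        zinb, label = tiny_untrained.decode(np.zeros(4))
        assert (zinb.nb.mean > 0).all() and (zinb.nb.dispersion > 0).all()
        assert ((zinb.dropout_prob >= 0) & (zinb.dropout_prob <= 1)).all()
        assert ((label > 0) & (label < 1)).all()  # Bernoulli head

    def test_decode_dimension_mismatch(self, tiny_untrained):
        with pytest.raises(ValueError, match="latent dimension"):
            tiny_untrained.decode(np.zeros((2, 9)))

    def test_decoded_zinb_samples_are_counts(self, trained_model, small_dataset):
        z = trained_model.encode(small_dataset["counts"].values[:5]).mean
        zinb, _ = trained_model.decode(z)
        x = cv.sample_zinb(
            cv.ZINBParams(cv.NBParams(zinb.nb.mean.ravel(), zinb.nb.dispersion.ravel()),
                          zinb.dropout_prob.ravel()),
            n=zinb.nb.mean.size, seed=0)
        assert (x >= 0).all() and np.issubdtype(x.dtype, np.integer)


class TestObjectives:
    def test_kl_term_nonnegative(self, tiny_untrained, tiny_batch):
        counts, _ = tiny_batch
        assert tiny_untrained.elbo_unsupervised(counts)["kl"] >= 0

    def test_gamma_zero_equals_unsupervised(self, tiny_untrained, tiny_batch):
        counts, labels = tiny_batch
        eps = [np.random.default_rng(2).standard_normal((3, 4))]
        elbo = tiny_untrained.elbo_unsupervised(counts, eps_list=eps)
        total = tiny_untrained.total_loss(counts, labels, gamma=0.0, eps_list=eps)
        assert total["total"] == pytest.approx(-elbo["elbo"], abs=1e-6)

    def test_all_false_mask_equals_unsupervised(self, tiny_untrained, tiny_batch):
        counts, labels = tiny_batch
        eps = [np.random.default_rng(3).standard_normal((3, 4))]
        elbo = tiny_untrained.elbo_unsupervised(counts, eps_list=eps)
        total = tiny_untrained.total_loss(counts, labels,
                                          label_mask=np.zeros(3, bool),
                                          gamma=5.0, eps_list=eps)
        assert total["total"] == pytest.approx(-elbo["elbo"], abs=1e-6)

    def test_affine_in_gamma(self, tiny_untrained, tiny_batch):
        counts, labels = tiny_batch
        eps = [np.random.default_rng(4).standard_normal((3, 4))]
        vals = [tiny_untrained.total_loss(counts, labels, gamma=g, eps_list=eps)["total"]
                for g in (0.0, 1.0, 3.5)]
        slope = vals[1] - vals[0]
        assert vals[2] == pytest.approx(vals[0] + 3.5 * slope, abs=1e-8)

    def test_manual_assembly_oracle(self, tiny_untrained, tiny_batch):
        # recompute every term of the objective by hand from decoded parameters
        counts, labels = tiny_batch
        mask = np.array([True, False, True])
        eps = [np.random.default_rng(5).standard_normal((3, 4))]
        parts = tiny_untrained.total_loss(counts, labels, mask, gamma=2.0, eps_list=eps)

        m = tiny_untrained
        code = m.encode(counts)
        kl = np.mean([cv.gaussian_kl_to_standard(
            cv.GaussianParams(code.mean[i], code.stddev[i])) for i in range(3)])
        z = code.mean + code.stddev * eps[0]
        zinb, bern_p = m.decode(z)
        recon = np.mean([
            cv.zinb_log_prob(counts[i].astype(int),
                             cv.ZINBParams(cv.NBParams(zinb.nb.mean[i],
                                                       zinb.nb.dispersion[i]),
                                           zinb.dropout_prob[i])).sum()
            for i in range(3)])
        bern_ll = labels * np.log(bern_p) + (1 - labels) * np.log1p(-bern_p)
        sup = -bern_ll.sum(axis=1)[mask].mean()
        expected = -(recon - kl) + 2.0 * sup
        assert parts["total"] == pytest.approx(expected, abs=1e-6)
        assert parts["kl"] == pytest.approx(kl, abs=1e-8)

    def test_mc_consistency(self, trained_model, small_dataset):
        counts = small_dataset["counts"].values[:64]
        singles = [trained_model.elbo_unsupervised(counts, n_mc_samples=1, seed=s)["elbo"]
                   for s in range(30)]
        big = trained_model.elbo_unsupervised(counts, n_mc_samples=100, seed=99)["elbo"]
        se = np.std(singles) / np.sqrt(len(singles))
        assert abs(np.mean(singles) - big) < 3 * se + np.std(singles) / 10

    def test_empty_batch_rejected(self, tiny_untrained):
        with pytest.raises(ValueError, match="non-empty"):
            tiny_untrained.elbo_unsupervised(np.zeros((0, 10)))


class TestFit:
    def test_loss_decreases(self, trained_model):
        h = trained_model.history_
        assert h["total"].iloc[-1] < h["total"].iloc[0]

    def test_seed_reproducibility(self, small_dataset, probabilized_labels):
        kw = dict(n_hidden_units=16, n_latent=4, max_epochs=3, patience=None, seed=3)
        runs = [SemiSupervisedVAE(**kw).fit(small_dataset["counts"].values,
                                            probabilized_labels).history_
                for _ in range(2)]
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_gamma_zero_matches_unlabeled_run(self, small_dataset, probabilized_labels):
        kw = dict(n_hidden_units=16, n_latent=4, max_epochs=3, patience=None, seed=4)
        with_labels = SemiSupervisedVAE(gamma=0.0, **kw).fit(
            small_dataset["counts"].values, probabilized_labels)
        without = SemiSupervisedVAE(gamma=0.0, **kw).fit(small_dataset["counts"].values)
        np.testing.assert_allclose(with_labels.history_["total"],
                                   without.history_["total"], rtol=1e-10)

    def test_label_fraction_mask_size(self, small_dataset, probabilized_labels):
        m = SemiSupervisedVAE(n_hidden_units=8, n_latent=4, max_epochs=1,
                              patience=None, label_fraction=0.3, seed=0)
        m.fit(small_dataset["counts"].values, probabilized_labels)
        assert m.label_mask_.sum() == round(0.3 * 200)

    def test_label_shape_mismatch(self, small_dataset):
        m = SemiSupervisedVAE(max_epochs=1)
        with pytest.raises(ValueError, match="number of cells"):
            m.fit(small_dataset["counts"].values, np.zeros((3, 2)))


class TestInference:
    def test_impute_nonnegative(self, trained_model, small_dataset):
        assert (trained_model.impute(small_dataset["counts"].values) >= 0).all()

    def test_impute_tracks_protein_signal(self, trained_model, small_dataset):
        from scipy.stats import spearmanr
        imputed = trained_model.impute(small_dataset["counts"].values)
        gene, protein = small_dataset["pairs"][0]
        gi = small_dataset["counts"].gene_ids.index(gene)
        pi = small_dataset["proteins"].protein_ids.index(protein)
        rho = spearmanr(imputed[:, gi], small_dataset["proteins"].values[:, pi])[0]
        assert rho > 0

    def test_impute_zero_when_dropout_forced(self, tiny_untrained):
        m = tiny_untrained
        m.params_["gene_bpi"].data[:] = 50.0  # pi -> 1 for every gene
        m.params_["gene_Wpi"].data[:] = 0.0
        np.testing.assert_allclose(m.impute(np.ones((2, 10), int)), 0.0, atol=1e-12)

    def test_nb_mean_mode_larger(self, trained_model, small_dataset):
        x = small_dataset["counts"].values[:10]
        assert (trained_model.impute(x, "nb_mean") >=
                trained_model.impute(x, "zinb_mean") - 1e-12).all()

    def test_predict_protein_range_and_determinism(self, trained_model, small_dataset):
        x = small_dataset["counts"].values[:1]
        p = trained_model.predict_protein(np.vstack([x, x]))
        assert ((p > 0) & (p < 1)).all()
        np.testing.assert_array_equal(p[0], p[1])

    def test_predict_protein_recovers_signal(self, trained_model, small_dataset):
        from scipy.stats import spearmanr
        pred = trained_model.predict_protein(small_dataset["counts"].values)
        rhos = [spearmanr(pred[:, j], small_dataset["proteins"].values[:, j])[0]
                for j in range(pred.shape[1])]
        assert np.mean(rhos) > 0.5

    def test_predict_without_head_rejected(self, small_dataset):
        m = SemiSupervisedVAE(n_hidden_units=8, n_latent=4, max_epochs=1,
                              patience=None).fit(small_dataset["counts"].values)
        with pytest.raises(RuntimeError, match="label head"):
            m.predict_protein(small_dataset["counts"].values)

    def test_nb_label_head(self, small_dataset):
        m = SemiSupervisedVAE(n_hidden_units=8, n_latent=4, max_epochs=2,
                              patience=None, label_likelihood="nb", seed=0)
        m.fit(small_dataset["counts"].values, small_dataset["proteins"].values)
        pred = m.predict_protein(small_dataset["counts"].values)
        assert (pred > 0).all() and np.isfinite(pred).all()


class TestMarginalLikelihood:
    def test_single_sample_is_elbo_draw(self, trained_model, small_dataset):
        counts = small_dataset["counts"].values[:8]
        mll = trained_model.marginal_log_likelihood(counts, 1, seed=0)
        assert np.isfinite(mll).all() and mll.shape == (8,)

    def test_finite_on_all_cells(self, trained_model, small_dataset):
        mll = trained_model.marginal_log_likelihood(
            small_dataset["counts"].values, 4, seed=1)
        assert np.isfinite(mll).all()

    def test_iwae_monotone_in_samples(self, trained_model, small_dataset):
        counts = small_dataset["counts"].values[:32]
        m1 = np.mean([trained_model.marginal_log_likelihood(counts, 1, seed=s).mean()
                      for s in range(50)])
        m64 = np.mean([trained_model.marginal_log_likelihood(counts, 64, seed=s).mean()
                       for s in range(10)])
        assert m64 >= m1

    def test_invalid_sample_count(self, trained_model, small_dataset):
        with pytest.raises(ValueError):
            trained_model.marginal_log_likelihood(small_dataset["counts"].values[:2], 0)


class TestCheckpoint:
    def test_save_load_roundtrip(self, trained_model, small_dataset, tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        loaded = SemiSupervisedVAE.load(path)
        x = small_dataset["counts"].values[:20]
        np.testing.assert_allclose(loaded.impute(x), trained_model.impute(x), atol=1e-12)
        np.testing.assert_allclose(loaded.predict_protein(x),
                                   trained_model.predict_protein(x), atol=1e-12)


def test_inference_never_reads_labels():
    """Evaluation-path purity: impute/encode/predict_protein accept counts only."""
    import inspect
    for method in (SemiSupervisedVAE.encode, SemiSupervisedVAE.impute,
                   SemiSupervisedVAE.predict_protein,
                   SemiSupervisedVAE.marginal_log_likelihood,
                   SemiSupervisedVAE.transform):
        params = inspect.signature(method).parameters
        assert not any(name in params for name in ("y", "labels", "label_mask")), method
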