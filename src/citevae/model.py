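"""Semisupervised variational autoencoder for single-cell counts.

The generative model ties a low-dimensional Gaussian latent code z to
two observation heads decoded from a shared trunk:

* a gene head emitting zero-inflated negative binomial (ZINB)
  parameters for the raw mRNA counts of every gene, and
* an optional label head emitting, per surface protein, either a
  Bernoulli probability (for probabilized protein labels in [0, 1])
  or a negative binomial mean (for raw ADT counts).

Training maximizes the evidence lower bound on the gene counts plus a
weighted supervised likelihood on the cells whose protein labels are
visible::

    loss = -ELBO(x) + gamma * mean_{labeled cells} NLL(y)

with ``gamma`` controlling how strongly protein supervision shapes the
shared representation; ``gamma = 0`` recovers the purely unsupervised
model. Labels are never consumed at inference time: encoding,
imputation and protein prediction take only the count matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import _autodiff as ad
from ._autodiff import Tensor
from .distributions import GaussianParams, NBParams, ZINBParams
from .io import CountMatrix, ProteinTable

logger = logging.getLogger(__name__)

_LOG_MEAN_CLIP = (-12.0, 14.0)  # log-scale decoder outputs, guards overflow
_LOGVAR_CLIP = (-10.0, 10.0)
_LOG_THETA_CLIP = (-6.0, 8.0)


@dataclass
class LatentCode:
    """Per-cell Gaussian posterior over the latent space."""

    mean: np.ndarray   # cells x n_latent
    stddev: np.ndarray

    def __post_init__(self):
        if np.any(self.stddev <= 0):
            raise ValueError("posterior stddev must be strictly positive")


def _as_counts(X) -> np.ndarray:
    if isinstance(X, CountMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("count matrix must be 2-D (cells x genes)")
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    return X


def _as_labels(y) -> np.ndarray:
    if isinstance(y, ProteinTable):
        y = y.values
    if isinstance(y, pd.DataFrame):
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    return y


class SemiSupervisedVAE(BaseEstimator):
    """ZINB variational autoencoder with an auxiliary protein head.

    Parameters
    ----------
    n_hidden_layers, n_hidden_units, n_latent : int
        Encoder/decoder architecture; the defaults (2 x 128 hidden,
        32 latent) are the tuned desk-scale design.
    label_likelihood : {"bernoulli", "nb"}
        Observation model of the protein head: Bernoulli for
        probabilized labels in [0, 1], NB for raw ADT counts.
    gamma : float
        Weight of the supervised protein loss. 0 disables supervision;
        values around 20 give a clear semisupervised benefit.
    label_fraction : float
        Fraction of cells whose labels are visible during training
        (seeded subset); emulates scarce labeling.
    n_mc_samples : int
        Monte-Carlo samples of z per ELBO evaluation during training.
    patience : int or None
        Early stopping patience on a held-out validation split
        (``validation_fraction`` of training cells); None trains for
        exactly ``max_epochs``.
    seed : int
        Controls initialization, label masking, the validation split,
        shuffling and reparameterization noise; runs are bitwise
        reproducible.

    Attributes
    ----------
    params_ : dict of str -> Tensor
        All trainable arrays.
    history_ : pandas.DataFrame
        Per-epoch loss components (reconstruction, kl, supervised,
        total, and validation total when early stopping is active).
    """

    def __init__(self, n_hidden_layers: int = 2, n_hidden_units: int = 128,
                 n_latent: int = 32, label_likelihood: str = "bernoulli",
                 gamma: float = 20.0, learning_rate: float = 1e-3,
                 batch_size: int = 128, max_epochs: int = 200,
                 patience: int | None = 20, validation_fraction: float = 0.1,
                 label_fraction: float = 1.0, n_mc_samples: int = 1,
                 seed: int = 0):
        self.n_hidden_layers = n_hidden_layers
        self.n_hidden_units = n_hidden_units
        self.n_latent = n_latent
        self.label_likelihood = label_likelihood
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.label_fraction = label_fraction
        self.n_mc_samples = n_mc_samples
        self.seed = seed

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------

    def _init_params(self, n_genes: int, n_proteins: int | None,
                     rng: np.random.Generator) -> None:
        if self.n_hidden_layers < 1 or self.n_hidden_units < 1 or self.n_latent < 1:
            raise ValueError("architecture sizes must be >= 1")
        if self.label_likelihood not in ("bernoulli", "nb"):
            raise ValueError("label_likelihood must be 'bernoulli' or 'nb'")

        def dense(n_in, n_out):
            scale = np.sqrt(2.0 / n_in)  # He init for relu layers
            return (Tensor(rng.normal(0, scale, (n_in, n_out)), requires_grad=True),
                    Tensor(np.zeros((1, n_out)), requires_grad=True))

        p: dict[str, Tensor] = {}
        sizes = [n_genes] + [self.n_hidden_units] * self.n_hidden_layers
        for i in range(self.n_hidden_layers):
            p[f"enc_W{i}"], p[f"enc_b{i}"] = dense(sizes[i], sizes[i + 1])
        p["enc_Wmu"], p["enc_bmu"] = dense(self.n_hidden_units, self.n_latent)
        p["enc_Wlv"], p["enc_blv"] = dense(self.n_hidden_units, self.n_latent)

        sizes = [self.n_latent] + [self.n_hidden_units] * self.n_hidden_layers
        for i in range(self.n_hidden_layers):
            p[f"dec_W{i}"], p[f"dec_b{i}"] = dense(sizes[i], sizes[i + 1])
        # gene head: linear projections of the shared trunk
        p["gene_Wmu"], p["gene_bmu"] = dense(self.n_hidden_units, n_genes)
        p["gene_Wpi"], p["gene_bpi"] = dense(self.n_hidden_units, n_genes)
        p["gene_log_theta"] = Tensor(np.zeros((1, n_genes)), requires_grad=True)
        if n_proteins is not None:
            p["label_W"], p["label_b"] = dense(self.n_hidden_units, n_proteins)
            if self.label_likelihood == "nb":
                p["label_log_theta"] = Tensor(np.zeros((1, n_proteins)), requires_grad=True)
        self.params_ = p
        self.n_genes_ = n_genes
        self.n_proteins_ = n_proteins

    def initialize(self, n_genes: int, n_proteins: int | None = None,
                   median_library: float = 1e4) -> "SemiSupervisedVAE":
        """Set up randomly initialized parameters without training.

        Useful for smoke checks and as an untrained control; all
        inference methods work (and stay finite) on the fresh state.
        """
        self._init_params(n_genes, n_proteins, np.random.default_rng(self.seed))
        self.median_library_ = float(median_library)
        self.label_mask_ = np.zeros(0, dtype=bool)
        self.history_ = pd.DataFrame()
        return self

    # ------------------------------------------------------------------
    # forward pieces (autodiff graph)
    # ------------------------------------------------------------------

    def _preprocess(self, counts: np.ndarray) -> np.ndarray:
        # library-size scaling + log1p; the decoder works on raw counts
        lib = counts.sum(axis=1, keepdims=True)
        lib = np.maximum(lib, 1.0)
        return np.log1p(counts / lib * self.median_library_)

    def _encode_graph(self, x_in: np.ndarray):
        p = self.params_
        h = Tensor(x_in)
        for i in range(self.n_hidden_layers):
            h = ad.relu(h @ p[f"enc_W{i}"] + p[f"enc_b{i}"])
        mu = h @ p["enc_Wmu"] + p["enc_bmu"]
        logvar = ad.clip(h @ p["enc_Wlv"] + p["enc_blv"], *_LOGVAR_CLIP)
        return mu, logvar

    def _decode_graph(self, z: Tensor):
        p = self.params_
        h = z
        for i in range(self.n_hidden_layers):
            h = ad.relu(h @ p[f"dec_W{i}"] + p[f"dec_b{i}"])
        log_mu = ad.clip(h @ p["gene_Wmu"] + p["gene_bmu"], *_LOG_MEAN_CLIP)
        pi_logit = h @ p["gene_Wpi"] + p["gene_bpi"]
        log_theta = ad.clip(p["gene_log_theta"], *_LOG_THETA_CLIP)
        label_out = None
        if self.n_proteins_ is not None:
            label_lin = h @ p["label_W"] + p["label_b"]
            if self.label_likelihood == "nb":
                label_out = (ad.clip(label_lin, *_LOG_MEAN_CLIP),
                             ad.clip(p["label_log_theta"], *_LOG_THETA_CLIP))
            else:
                label_out = label_lin  # Bernoulli logits
        return log_mu, pi_logit, log_theta, label_out

    @staticmethod
    def _zinb_ll_graph(x: np.ndarray, log_mu: Tensor, log_theta: Tensor,
                       pi_logit: Tensor) -> Tensor:
        """Per-cell ZINB log-likelihood, summed over genes (Tensor, shape (B,))."""
        theta = ad.exp(log_theta)
        log_theta_mu = ad.logaddexp(log_theta, log_mu)
        nb_ll = (
            ad.lgamma(theta + x) - ad.lgamma(theta)
            + Tensor(-gammaln(x + 1.0))
            + theta * (log_theta - log_theta_mu)
            + Tensor(x) * (log_mu - log_theta_mu)
        )
        # zero entries: log(pi + (1-pi)*NB(0)) written via the dropout logit
        sp_logit = ad.softplus(pi_logit)
        zero_case = ad.logaddexp(pi_logit, nb_ll) - sp_logit
        nonzero_case = nb_ll - sp_logit
        is_zero = (x == 0).astype(float)
        ll = Tensor(is_zero) * zero_case + Tensor(1.0 - is_zero) * nonzero_case
        return ll.sum(axis=1)

    def _label_nll_graph(self, y: np.ndarray, label_out) -> Tensor:
        """Per-cell supervised negative log-likelihood, summed over proteins."""
        if self.label_likelihood == "bernoulli":
            logits = label_out
            ll = Tensor(y) * logits - ad.softplus(logits)
        else:
            log_mu, log_theta = label_out
            theta = ad.exp(log_theta)
            log_theta_mu = ad.logaddexp(log_theta, log_mu)
            ll = (
                ad.lgamma(theta + y) - ad.lgamma(theta)
                + Tensor(-gammaln(y + 1.0))
                + theta * (log_theta - log_theta_mu)
                + Tensor(y) * (log_mu - log_theta_mu)
            )
        return -ll.sum(axis=1)

    def _loss_graph(self, counts: np.ndarray, y: np.ndarray | None,
                    mask: np.ndarray | None, gamma: float,
                    eps_list: list[np.ndarray]):
        """Build the full objective; returns (total Tensor, float parts)."""
        x_in = self._preprocess(counts)
        q_mu, q_logvar = self._encode_graph(x_in)
        kl_per_cell = (0.5 * (q_mu * q_mu + ad.exp(q_logvar) - 1.0 - q_logvar)).sum(axis=1)
        kl = kl_per_cell.mean()

        recon_terms, sup_terms = [], []
        for eps in eps_list:
            z = q_mu + ad.exp(0.5 * q_logvar) * Tensor(eps)
            log_mu, pi_logit, log_theta, label_out = self._decode_graph(z)
            recon_terms.append(self._zinb_ll_graph(counts, log_mu, log_theta, pi_logit))
            if y is not None and mask is not None and mask.any():
                nll = self._label_nll_graph(y, label_out)
                # averaged over labeled cells only, so gamma is comparable
                # across label fractions
                sup_terms.append((nll * Tensor(mask.astype(float))).sum()
                                 * (1.0 / float(mask.sum())))

        s = float(len(eps_list))
        recon = sum(recon_terms[1:], recon_terms[0]).mean() * (1.0 / s)
        neg_elbo = -(recon - kl)
        if sup_terms:
            sup = sum(sup_terms[1:], sup_terms[0]) * (1.0 / s)
            total = neg_elbo + gamma * sup
        else:
            sup = None
            total = neg_elbo
        parts = {
            "reconstruction": float(recon.data),
            "kl": float(kl.data),
            "supervised": float(sup.data) if sup is not None else 0.0,
            "total": float(total.data),
        }
        return total, parts

    # ------------------------------------------------------------------
    # public objectives
    # ------------------------------------------------------------------

    def elbo_unsupervised(self, counts, eps_list=None, n_mc_samples: int | None = None,
                          seed: int | None = None) -> dict:
        """Monte-Carlo ELBO estimate on a batch; returns its parts.

        ``reconstruction`` is E_q[log p(x|z)], ``kl`` the analytic
        KL(q(z|x) || N(0,I)); ``elbo = reconstruction - kl``.
        ``eps_list`` fixes the reparameterization noise so that two
        objectives can be compared on identical samples.
        """
        check_is_fitted(self, "params_")
        counts = _as_counts(counts)
        if counts.shape[0] == 0:
            raise ValueError("batch must be non-empty")
        eps_list = self._make_eps(counts.shape[0], eps_list, n_mc_samples, seed)
        _, parts = self._loss_graph(counts, None, None, 0.0, eps_list)
        return {
            "reconstruction": parts["reconstruction"],
            "kl": parts["kl"],
            "elbo": parts["reconstruction"] - parts["kl"],
        }

    def total_loss(self, counts, labels=None, label_mask=None,
                   gamma: float | None = None, eps_list=None,
                   n_mc_samples: int | None = None, seed: int | None = None) -> dict:
        """The semisupervised objective on a batch (to be minimized).

        ``total = -ELBO + gamma * mean over masked cells of label NLL``;
        cells outside the mask contribute only the unsupervised part.
        """
        check_is_fitted(self, "params_")
        counts = _as_counts(counts)
        gamma = self.gamma if gamma is None else gamma
        y = _as_labels(labels) if labels is not None else None
        if y is not None and label_mask is None:
            label_mask = np.ones(counts.shape[0], dtype=bool)
        if label_mask is not None:
            label_mask = np.asarray(label_mask, dtype=bool)
        if y is not None and label_mask is not None and not label_mask.all():
            if np.any(np.abs(y[~label_mask]) > 0):
                logger.warning("labels provided for unmasked cells are ignored")
        eps_list = self._make_eps(counts.shape[0], eps_list, n_mc_samples, seed)
        _, parts = self._loss_graph(counts, y, label_mask, gamma, eps_list)
        return parts

    def _make_eps(self, n_cells, eps_list, n_mc_samples, seed):
        if eps_list is not None:
            return [np.asarray(e, dtype=float) for e in eps_list]
        s = n_mc_samples if n_mc_samples is not None else self.n_mc_samples
        rng = np.random.default_rng(self.seed if seed is None else seed)
        return [rng.standard_normal((n_cells, self.n_latent)) for _ in range(s)]

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        """Train on a cells x genes count matrix, optionally with labels.

        ``y`` is a cells x proteins array of supervision targets —
        probabilized labels in [0, 1] for the Bernoulli head, raw ADT
        counts for the NB head. A seeded ``label_fraction`` subset of
        cells is marked label-visible; the rest train unsupervised.
        """
        counts = _as_counts(X)
        n_cells, n_genes = counts.shape
        # independent streams per purpose, so e.g. a gamma=0 run with labels
        # consumes the same training noise as a run without labels
        rng_init, rng_mask, rng_split, rng = [
            np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(4)]
        self.median_library_ = float(np.median(np.maximum(counts.sum(axis=1), 1.0)))

        yv = _as_labels(y) if y is not None else None
        if yv is not None and yv.shape[0] != n_cells:
            raise ValueError("labels and counts disagree on the number of cells")
        self._init_params(n_genes, yv.shape[1] if yv is not None else None, rng_init)

        # label visibility mask (seeded), before any batching
        mask = np.zeros(n_cells, dtype=bool)
        if yv is not None:
            if not (0.0 <= self.label_fraction <= 1.0):
                raise ValueError("label_fraction must lie in [0, 1]")
            n_vis = int(round(self.label_fraction * n_cells))
            mask[rng_mask.permutation(n_cells)[:n_vis]] = True
        self.label_mask_ = mask

        # optional validation split for early stopping
        idx = rng_split.permutation(n_cells)
        use_val = self.patience is not None and n_cells >= 20
        n_val = int(round(self.validation_fraction * n_cells)) if use_val else 0
        val_idx, train_idx = idx[:n_val], idx[n_val:]

        opt = ad.Adam(self.params_.values(), lr=self.learning_rate)
        history: list[dict] = []
        best_val, best_snapshot, stall = np.inf, None, 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(train_idx)
            sums = {"reconstruction": 0.0, "kl": 0.0, "supervised": 0.0, "total": 0.0}
            n_batches = 0
            for start in range(0, order.size, self.batch_size):
                rows = order[start:start + self.batch_size]
                eps_list = [rng.standard_normal((rows.size, self.n_latent))
                            for _ in range(self.n_mc_samples)]
                total, parts = self._loss_graph(
                    counts[rows], yv[rows] if yv is not None else None,
                    mask[rows] if yv is not None else None, self.gamma, eps_list)
                if not np.isfinite(parts["total"]):
                    bad = [k for k, v in parts.items() if not np.isfinite(v)]
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: offending terms {bad}")
                opt.zero_grad()
                total.backward()
                opt.step()
                for k in sums:
                    sums[k] += parts[k]
                n_batches += 1
            row = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()}}
            if use_val:
                eps_val = [rng.standard_normal((val_idx.size, self.n_latent))]
                _, vparts = self._loss_graph(
                    counts[val_idx], yv[val_idx] if yv is not None else None,
                    mask[val_idx] if yv is not None else None, self.gamma, eps_val)
                row["val_total"] = vparts["total"]
                if vparts["total"] < best_val - 1e-9:
                    best_val, stall = vparts["total"], 0
                    best_snapshot = {k: t.data.copy() for k, t in self.params_.items()}
                else:
                    stall += 1
            history.append(row)
            if use_val and stall >= self.patience:
                break
        if best_snapshot is not None:
            for k, t in self.params_.items():
                t.data = best_snapshot[k]
        self.history_ = pd.DataFrame(history)
        return self

    # ------------------------------------------------------------------
    # inference (labels are never inputs here)
    # ------------------------------------------------------------------

    def encode(self, X) -> LatentCode:
        """Posterior Gaussian q(z|x) per cell; deterministic given the state."""
        check_is_fitted(self, "params_")
        counts = _as_counts(X)
        if counts.shape[1] != self.n_genes_:
            raise ValueError(
                f"gene dimension {counts.shape[1]} does not match training ({self.n_genes_})")
        mu, logvar = self._encode_graph(self._preprocess(counts))
        return LatentCode(mean=mu.data, stddev=np.exp(0.5 * logvar.data))

    def transform(self, X) -> np.ndarray:
        """Latent posterior means (the representation used downstream)."""
        return self.encode(X).mean

    def decode(self, z):
        """Decode latent vectors into observation-model parameters.

        Returns ``(ZINBParams, label_params)`` where ``label_params``
        is a Bernoulli probability matrix, an ``NBParams``, or None if
        the model was trained without a label head.
        """
        check_is_fitted(self, "params_")
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            z = z[None, :]
        if z.shape[1] != self.n_latent:
            raise ValueError(f"latent dimension {z.shape[1]} != {self.n_latent}")
        log_mu, pi_logit, log_theta, label_out = self._decode_graph(Tensor(z))
        zinb = ZINBParams(
            nb=NBParams(mean=np.exp(log_mu.data),
                        dispersion=np.broadcast_to(np.exp(log_theta.data),
                                                   log_mu.data.shape).copy()),
            dropout_prob=expit(pi_logit.data),
        )
        if label_out is None:
            label_params = None
        elif self.label_likelihood == "bernoulli":
            label_params = expit(label_out.data)
        else:
            lm, lt = label_out
            label_params = NBParams(mean=np.exp(lm.data),
                                    dispersion=np.broadcast_to(np.exp(lt.data),
                                                               lm.data.shape).copy())
        return zinb, label_params

    def impute(self, X, mode: str = "zinb_mean") -> np.ndarray:
        """Denoised expression: expected ZINB value at the posterior mean of z.

        ``mode="zinb_mean"`` returns ``(1 - pi) * mu`` (the default);
        ``mode="nb_mean"`` returns ``mu`` alone.
        """
        check_is_fitted(self, "params_")
        zinb, _ = self.decode(self.encode(X).mean)
        if mode == "zinb_mean":
            return (1.0 - zinb.dropout_prob) * zinb.nb.mean
        if mode == "nb_mean":
            return zinb.nb.mean
        raise ValueError("mode must be 'zinb_mean' or 'nb_mean'")

    def predict_protein(self, X) -> np.ndarray:
        """Expected protein response per cell, from counts alone.

        Bernoulli head: probability of each protein being "on";
        NB head: expected ADT count.
        """
        check_is_fitted(self, "params_")
        if self.n_proteins_ is None:
            raise RuntimeError("model was trained without a label head")
        _, label_params = self.decode(self.encode(X).mean)
        if self.label_likelihood == "bernoulli":
            return label_params
        return label_params.mean

    def marginal_log_likelihood(self, X, n_importance_samples: int = 64,
                                seed: int | None = None) -> np.ndarray:
        """Importance-weighted marginal log-likelihood estimate per cell.

        ``log (1/S) sum_s p(x|z_s) p(z_s) / q(z_s|x)`` with z_s drawn
        from the encoder posterior; non-decreasing in expectation as S
        grows, and at S=1 it is a single-sample ELBO draw.
        """
        check_is_fitted(self, "params_")
        if n_importance_samples < 1:
            raise ValueError("n_importance_samples must be >= 1")
        counts = _as_counts(X)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        mu, logvar = self._encode_graph(self._preprocess(counts))
        q_mu, q_logvar = mu.data, logvar.data
        q_sd = np.exp(0.5 * q_logvar)
        log_ws = np.empty((n_importance_samples, counts.shape[0]))
        for s in range(n_importance_samples):
            eps = rng.standard_normal(q_mu.shape)
            z = q_mu + q_sd * eps
            log_mu_x, pi_logit, log_theta, _ = self._decode_graph(Tensor(z))
            log_px_z = self._zinb_ll_graph(counts, log_mu_x, log_theta, pi_logit).data
            log_pz = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
            log_qz = -0.5 * np.sum(eps**2 + np.log(2 * np.pi) + q_logvar, axis=1)
            log_ws[s] = log_px_z + log_pz - log_qz
        return logsumexp(log_ws, axis=0) - np.log(n_importance_samples)

    # ------------------------------------------------------------------
    # checkpointing
    # ------------------------------------------------------------------

    def save(self, path) -> None:
        """Write a single .npz archive: architecture config + parameter arrays."""
        check_is_fitted(self, "params_")
        config = json.dumps({
            **self.get_params(),
            "n_genes": self.n_genes_,
            "n_proteins": self.n_proteins_,
            "median_library": self.median_library_,
        })
        arrays = {k: t.data for k, t in self.params_.items()}
        np.savez(path, __config__=np.array(config), **arrays)

    @classmethod
    def load(cls, path) -> "SemiSupervisedVAE":
        with np.load(path, allow_pickle=False) as archive:
            config = json.loads(str(archive["__config__"]))
            arrays = {k: archive[k] for k in archive.files if k != "__config__"}
        n_genes = config.pop("n_genes")
        n_proteins = config.pop("n_proteins")
        median_library = config.pop("median_library")
        est = cls(**config)
        est._init_params(n_genes, n_proteins, np.random.default_rng(est.seed))
        for k, t in est.params_.items():
            t.data = arrays[k]
        est.median_library_ = median_library
        est.history_ = pd.DataFrame()
        return est


# ----------------------------------------------------------------------
# thin functional wrappers
# ----------------------------------------------------------------------

def encode(model: SemiSupervisedVAE, counts) -> LatentCode:
    return model.encode(counts)


def decode(model: SemiSupervisedVAE, z):
    return model.decode(z)


def elbo_unsupervised(model: SemiSupervisedVAE, counts, **kw) -> dict:
    return model.elbo_unsupervised(counts, **kw)


def total_loss(model: SemiSupervisedVAE, counts, labels=None, label_mask=None,
               gamma=None, **kw) -> dict:
    return model.total_loss(counts, labels, label_mask, gamma, **kw)


def fit(model: SemiSupervisedVAE, counts, labels=None) -> SemiSupervisedVAE:
    return model.fit(counts, labels)


def impute(model: SemiSupervisedVAE, counts, mode: str = "zinb_mean") -> np.ndarray:
    return model.impute(counts, mode)


def predict_protein(model: SemiSupervisedVAE, counts) -> np.ndarray:
    return model.predict_protein(counts)


def marginal_log_likelihood(model: SemiSupervisedVAE, counts,
                            n_importance_samples: int = 64, seed=None) -> np.ndarray:
    return model.marginal_log_likelihood(counts, n_importance_samples, seed)
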