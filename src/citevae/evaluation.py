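"""Evaluation metrics: marker correlations, latent-space classification
and clustering quality, and report assembly.

Marker gene/protein pairs give an unbiased readout of denoising
quality: surface-protein levels are nearly dropout-free, so a
well-imputed marker gene should track its protein across cells. The
latent space is scored by a secondary classifier (macro F1) and by a
pooled clustering index averaging ARI, NMI, rescaled silhouette and
unsupervised clustering accuracy (UCA), all in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr, spearmanr
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (adjusted_rand_score, f1_score,
                             normalized_mutual_info_score, silhouette_score)

logger = logging.getLogger(__name__)


def _pair_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Mean of Pearson and Spearman correlation; 0 if either is degenerate."""
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance vector in a marker pair; scoring it 0")
        return 0.0
    return 0.5 * (pearsonr(x, y)[0] + spearmanr(x, y)[0])


def marker_correlation(imputed: pd.DataFrame, proteins: pd.DataFrame, pairs):
    """Combined Pearson+Spearman score over designated marker pairs.

    Parameters
    ----------
    imputed : DataFrame, cells x genes (denoised expression)
    proteins : DataFrame, cells x proteins (measured, e.g. CLR)
    pairs : iterable of (gene_id, protein_id)

    Returns the mean over all pairs (and both statistics) together
    with the per-pair scores.
    """
    shared = imputed.index.intersection(proteins.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared cells")
    per_pair = {}
    for gene, protein in pairs:
        if gene not in imputed.columns:
            raise KeyError(f"gene {gene!r} missing from imputed matrix")
        if protein not in proteins.columns:
            raise KeyError(f"protein {protein!r} missing from protein table")
        per_pair[(gene, protein)] = _pair_correlation(
            imputed.loc[shared, gene].to_numpy(dtype=float),
            proteins.loc[shared, protein].to_numpy(dtype=float),
        )
    return float(np.mean(list(per_pair.values()))), per_pair


def latent_classifier_f1(z_train, targets_train, z_eval=None, targets_eval=None,
                         seed: int = 0) -> float:
    """Macro-averaged F1 of a secondary classifier on latent codes.

    A multinomial L2-regularized logistic regression is trained on
    the training-split latent means; F1 is reported on the evaluation
    split (defaults to the training split itself). 2-D binary targets
    are treated as multilabel: one classifier per protein, scores
    averaged; columns with a single class in training are excluded.
    """
    z_train = np.asarray(z_train, dtype=float)
    if z_eval is None:
        z_eval, targets_eval = z_train, targets_train
    z_eval = np.asarray(z_eval, dtype=float)
    t_train, t_eval = np.asarray(targets_train), np.asarray(targets_eval)

    def one(tr, ev):
        if np.unique(tr).size < 2:
            return None
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(z_train, tr)
        return f1_score(ev, clf.predict(z_eval), average="macro")

    if t_train.ndim == 2:
        scores = []
        for j in range(t_train.shape[1]):
            s = one(t_train[:, j], t_eval[:, j])
            if s is None:
                logger.warning("target column %d has one class in train; excluded", j)
            else:
                scores.append(s)
        if not scores:
            raise ValueError("no target column with two classes in the training split")
        return float(np.mean(scores))
    s = one(t_train, t_eval)
    if s is None:
        raise ValueError("training targets contain a single class")
    return float(s)


def unsupervised_clustering_accuracy(true_labels, cluster_labels) -> float:
    """Accuracy under the optimal one-to-one cluster-to-label assignment."""
    # contingency table (classes x clusters may be rectangular, and the
    # two label alphabets need not coincide)
    cm = pd.crosstab(np.asarray(true_labels), np.asarray(cluster_labels)).to_numpy()
    rows, cols = linear_sum_assignment(-cm)
    return float(cm[rows, cols].sum() / cm.sum())


def clustering_score(z, true_labels, k: int | None = None, seed: int = 0) -> dict:
    """Pooled latent clustering quality against true categorical labels.

    K-means (k = number of true classes unless given, 10 seeded
    restarts) partitions the latent means; ARI and NMI compare the
    partition to the labels, silhouette measures latent geometry
    (rescaled to [0, 1] via (ASW+1)/2), and UCA is the accuracy under
    the best cluster-to-label matching. ``pooled`` is their unweighted
    mean, in [0, 1].
    """
    z = np.asarray(z, dtype=float)
    true_labels = np.asarray(true_labels)
    if k is None:
        k = np.unique(true_labels).size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > z.shape[0]:
        raise ValueError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)
    pred = km.labels_
    ari = adjusted_rand_score(true_labels, pred)
    nmi = normalized_mutual_info_score(true_labels, pred)
    asw = silhouette_score(z, pred) if np.unique(pred).size > 1 else 0.0
    uca = unsupervised_clustering_accuracy(true_labels, pred)
    pooled = float(np.mean([ari, nmi, (asw + 1) / 2, uca]))
    return {"ari": float(ari), "nmi": float(nmi), "asw": float((asw + 1) / 2),
            "uca": float(uca), "pooled": pooled}


@dataclass
class EvalReport:
    """Per-split metric values plus run metadata."""

    metrics: dict = field(default_factory=dict)  # split -> {metric: value}
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"metrics": self.metrics, "metadata": self.metadata}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(metrics=d["metrics"], metadata=d["metadata"])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"split": s, "metric": m, "value": v}
                for s, mm in self.metrics.items() for m, v in mm.items()]
        return pd.DataFrame(rows)


def assemble_report(model, counts, train_cells, test_cells, proteins=None,
                    pairs=None, labels=None, n_importance_samples: int = 16,
                    seed: int = 0) -> EvalReport:
    """Run the full metric battery on train and test splits.

    ``counts`` is a CountMatrix; ``proteins`` a cells x proteins
    DataFrame on the evaluation scale (e.g. CLR); ``labels`` a
    pandas Series of cell types indexed by cell id. Metrics whose
    inputs are absent are skipped and logged, never failed.
    """
    from .io import CountMatrix  # local import to avoid a cycle

    assert isinstance(counts, CountMatrix)
    metrics: dict[str, dict] = {}
    z_train = model.transform(counts.subset_cells(train_cells).values)
    for split, ids in (("train", train_cells), ("test", test_cells)):
        sub = counts.subset_cells(ids)
        out: dict[str, float] = {}
        z = model.transform(sub.values)
        if proteins is not None and pairs:
            imputed = pd.DataFrame(model.impute(sub.values), index=ids,
                                   columns=counts.gene_ids)
            out["marker_correlation"], _ = marker_correlation(
                imputed, proteins.loc[ids], pairs)
            if getattr(model, "n_proteins_", None) is not None:
                pred = pd.DataFrame(model.predict_protein(sub.values), index=ids,
                                    columns=list(proteins.columns))
                scores = [
                    _pair_correlation(pred[p].to_numpy(), proteins.loc[ids, p].to_numpy())
                    for p in proteins.columns
                ]
                out["protein_prediction_correlation"] = float(np.mean(scores))
        else:
            logger.info("no protein table: marker and prediction metrics skipped")
        if labels is not None:
            lbl = pd.Series(labels)
            out["latent_f1"] = latent_classifier_f1(
                z_train, lbl.loc[train_cells].to_numpy(), z, lbl.loc[ids].to_numpy(),
                seed=seed)
            out.update({f"clustering_{k}": v for k, v in clustering_score(
                z, lbl.loc[ids].to_numpy(), seed=seed).items()})
        out["marginal_log_likelihood"] = float(np.mean(
            model.marginal_log_likelihood(sub.values, n_importance_samples, seed=seed)))
        metrics[split] = out
    config = json.dumps(model.get_params(), sort_keys=True, default=str)
    return EvalReport(
        metrics=metrics,
        metadata={
            "seed": seed,
            "config_hash": hashlib.sha256(config.encode()).hexdigest()[:12],
            "n_cells": {"train": len(train_cells), "test": len(test_cells)},
        },
    )
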