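"""Binomial-downsampling corruption benchmark for imputation robustness.

The protocol: select an exact fraction of count-matrix entries
uniformly without replacement and replace each selected entry holding
count n with a Binomial(n, keep_prob) draw — i.e. downsample it —
then train on the corrupted data and score the denoised output
against the original, uncorrupted data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .evaluation import clustering_score, marker_correlation
from .gating import ProteinGating
from .io import CountMatrix, ProteinTable, clr_normalize, split_train_test


@dataclass
class CorruptionSpec:
    """Corruption protocol parameters.

    fraction : exact share of matrix entries replaced (default 25%).
    keep_prob : binomial success probability of the downsampling draw
        (default 0.2, i.e. each selected entry keeps each of its n
        counts with probability 0.2).
    """

    fraction: float = 0.25
    keep_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        if not (0.0 < self.keep_prob < 1.0):
            raise ValueError("keep_prob must lie in (0, 1)")


def corrupt_counts(counts: CountMatrix, spec: CorruptionSpec | None = None):
    """Downsample an exact fraction of entries; returns (corrupted, mask).

    Exactly ``round(fraction * n_entries)`` entries are selected
    without replacement (zeros included); every corrupted entry is
    <= its original value and the matrix stays integer.
    """
    spec = spec or CorruptionSpec()
    rng = np.random.default_rng(spec.seed)
    values = counts.values.copy()
    n_entries = values.size
    k = int(round(spec.fraction * n_entries))
    flat_idx = rng.choice(n_entries, size=k, replace=False)
    mask = np.zeros(n_entries, dtype=bool)
    mask[flat_idx] = True
    mask = mask.reshape(values.shape)
    values[mask] = rng.binomial(values[mask], spec.keep_prob)
    return CountMatrix(values, counts.cell_ids, counts.gene_ids), mask


class IdentityModel:
    """Control "model" that returns its input unchanged (no denoising)."""

    def fit(self, X, y=None):
        return self

    def impute(self, X):
        return X.values if isinstance(X, CountMatrix) else np.asarray(X, dtype=float)


class OracleModel:
    """Control "model" that returns the original, uncorrupted counts."""

    def __init__(self, original: CountMatrix):
        self.original = original

    def fit(self, X, y=None):
        return self

    def impute(self, X):
        cells = X.cell_ids if isinstance(X, CountMatrix) else self.original.cell_ids
        return self.original.subset_cells(cells).values.astype(float)


def run_corruption_benchmark(
    counts: CountMatrix,
    configs: dict,
    spec: CorruptionSpec | None = None,
    proteins: ProteinTable | None = None,
    pairs=None,
    labels=None,
    train_fraction: float = 0.9,
    n_clusters: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Corrupt, train each configuration, score against the original.

    ``configs`` maps a name to a model object exposing ``fit(X, y)``
    and ``impute(X)`` (e.g. a SemiSupervisedVAE, or the Identity/
    Oracle controls). Semisupervised models receive probabilized
    protein labels when ``proteins`` is given. Metrics (marker
    correlation against measured proteins; pooled latent clustering
    against ``labels`` when the model exposes ``transform``) are
    computed per train/test split against the ORIGINAL data.

    Returns a tidy frame with columns (config, split, metric, value).
    """
    if not configs:
        raise ValueError("need at least one model configuration")
    spec = spec or CorruptionSpec()
    corrupted, _ = corrupt_counts(counts, spec)
    train_ids, test_ids = split_train_test(counts.cell_ids, train_fraction, seed)

    y_prob = None
    if proteins is not None:
        gate = ProteinGating().fit(proteins.to_frame())
        y_prob = pd.DataFrame(gate.transform(proteins.to_frame()),
                              index=proteins.cell_ids, columns=proteins.protein_ids)
        protein_eval = clr_normalize(proteins) if proteins.scale == "raw" else proteins
    if labels is not None:
        labels = pd.Series(np.asarray(labels), index=counts.cell_ids)

    rows = []
    for name, template in configs.items():
        model = clone(template) if hasattr(template, "get_params") else template
        train_corrupt = corrupted.subset_cells(train_ids)
        uses_labels = y_prob is not None and getattr(model, "gamma", 0) > 0
        try:
            model.fit(train_corrupt.values,
                      y_prob.loc[train_ids].to_numpy() if uses_labels else None)
        except TypeError:
            model.fit(train_corrupt)
        for split, ids in (("train", train_ids), ("test", test_ids)):
            sub = corrupted.subset_cells(ids)
            imputed = model.impute(sub if isinstance(model, (IdentityModel, OracleModel))
                                   else sub.values)
            imputed = pd.DataFrame(np.asarray(imputed), index=ids,
                                   columns=counts.gene_ids)
            if proteins is not None and pairs:
                score, _ = marker_correlation(imputed,
                                              protein_eval.to_frame().loc[ids], pairs)
                rows.append({"config": name, "split": split,
                             "metric": "marker_correlation", "value": score})
            if labels is not None and hasattr(model, "transform"):
                z = model.transform(sub.values)
                k = n_clusters or labels.nunique()
                cs = clustering_score(z, labels.loc[ids].to_numpy(), k=k, seed=seed)
                rows.append({"config": name, "split": split,
                             "metric": "pooled_clustering", "value": cs["pooled"]})
    return pd.DataFrame(rows)
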