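# Methods

This note states the model implemented in `citevae`, the choices behind its
defaults, and the limits of the synthetic data generator used to study it.

## Observation model

Gene counts are modeled per cell with a zero-inflated negative binomial
(ZINB). The negative binomial is parameterized by mean `mu > 0` and
dispersion `theta > 0` with variance `mu + mu^2 / theta`; equivalently
`r = theta`, `p = theta / (theta + mu)`. Zero inflation mixes in a point
mass at zero with probability `pi`:

```
log p(x)  =  log( pi + (1 - pi) * NB(0 | mu, theta) )      if x = 0
          =  log(1 - pi) + log NB(x | mu, theta)           if x > 0
```

All likelihoods are evaluated in log space. Inside the training graph, the
zero branch is computed from the dropout *logit* `l` as
`logaddexp(l, log NB(0)) - softplus(l)` and the positive branch as
`log NB(x) - softplus(l)`, which is finite for any `l`. Dispersion is a free
per-gene parameter shared across cells: with a handful of cells per gene per
batch there is not enough signal to condition `theta` on the latent state,
and a shared per-gene value matches how overdispersion is usually estimated
from replicates.

## Variational autoencoder

The encoder maps preprocessed expression to a diagonal Gaussian
`q(z | x) = N(mu_z, diag(sigma_z^2))`; the decoder maps a latent sample
(reparameterized, `z = mu_z + sigma_z * eps`) back to per-gene ZINB
parameters `(mu, pi)` on the raw count scale. The unsupervised objective is
the negative evidence lower bound,

```
-ELBO = - E_q[ log p(x | z) ] + KL( q(z|x) || N(0, I) )
```

with the KL in closed form. Encoder input is
`log1p(x / libsize * median_libsize)`: library-size scaling removes depth as
the dominant axis of variation, `log1p` compresses the dynamic range, and
the *decoder* still reconstructs raw counts so the ZINB likelihood is
honest. Model quality is reported as an importance-weighted bound,
`log (1/S) sum_s w_s` with `w_s = p(x, z_s) / q(z_s | x)` computed by
`logsumexp`; it is a lower bound on `log p(x)` that tightens monotonically
in `S` (checked in the tests at `S` = 1 vs 64).

## Protein gating

Each protein's ADT values (optionally `log1p`-library-normalized,
the default) are fit with a two-component univariate Gaussian mixture by EM:

- deterministic initialization at the 25th/75th percentiles with the pooled
  variance, so fits are reproducible without restarts;
- a variance floor of `1e-6` times the data variance to prevent component
  collapse;
- a per-iteration log-likelihood trace, asserted monotone in the tests and
  cross-checked against scikit-learn's `GaussianMixture`.

The "on" component is the one with the larger mean. The probabilistic label
is the posterior probability of the on component (Bayes rule); `binarize`
thresholds it at 0.5. Gating is scale-equivariant: fitting `c * x` yields
scaled parameters and identical posteriors, so proteins measured on very
different count scales land on the same [0, 1] scale.

## Semisupervised objective

A second decoder head predicts the gated labels `y in [0, 1]^P` from the
same latent code, with a Bernoulli likelihood on the probabilistic labels
(or negative binomial for raw ADT counts). The training loss is

```
L = -ELBO + gamma * mean_{labeled cells} [ -log p(y | z) ]
```

with a single uniform weighted sum over proteins. The loss is affine in
`gamma`, and `gamma = 0` reproduces the unsupervised model exactly: the
fitting routine draws parameter initialization, the label-visibility mask,
the validation split and training noise from four independent streams
spawned from one seed, so a `gamma = 0` run with labels and a run without
labels consume identical randomness and produce bitwise-identical loss
curves. `label_fraction` controls how many cells (chosen at random, seeded)
expose their labels, enabling semisupervision studies.

## Optimization and defaults

Networks are two hidden layers of 128 ReLU units (He initialization), latent
dimension 32, trained with Adam at learning rate 1e-3, batch size 128, up to
200 epochs with early stopping (patience 20) on a 10% validation split, one
Monte Carlo sample per step. `gamma = 20` balances a label term that is
orders of magnitude smaller than the reconstruction term (a few proteins vs
hundreds of genes). Gradients come from a small built-in reverse-mode
autodiff engine (numpy + scipy special functions) because the package
targets environments without a deep-learning framework; its gradients are
finite-difference-checked to ~1e-9 relative error in the test suite.
Internal clamps (log-mean in [-12, 14], log-variance in [-10, 10],
log-dispersion in [-6, 8]) keep `exp` and `lgamma` finite on extreme inputs;
they act as straight-through identities inside the bounds.

## Synthetic data generator

`simulate` draws cell types from given proportions, per-gene base means
(log-uniform, clipped to [0.5, 50]), per-gene dispersions in [1, 10], and
dropout probabilities from logits in [-2, 0]. A fraction (0.2) of genes get
a fold-change (4x) in each type; marker genes and their paired proteins are
elevated (8x) in one shared type. Proteins are negative binomial
(base mean 20, dispersion 10) without dropout — ADT counts are much less
sparse than mRNA. Defaults: 500 cells, 100 genes, 5 proteins, 3 types, 5
marker pairs. These are study conditions, not tuned quantities.

Limits: the generator has no batch effects, no library-size gradients
confounded with type, no ambient contamination, no doublets, and
type effects are independent across genes; absolute metric values on it will
be optimistic relative to real CITE-seq data. It is designed so that the
*comparison* between `gamma > 0` and `gamma = 0` is meaningful, not so that
absolute numbers transfer.

## Corruption benchmark

Exactly `round(0.25 * n_entries)` count-matrix entries are selected
uniformly without replacement (zeros included) and each selected entry `n`
is replaced by a `Binomial(n, 0.2)` draw. Models are trained on the
corrupted matrix and scored against the *uncorrupted* proteins and labels;
an identity model (returns its input) and an oracle (returns the clean
counts) bracket the achievable range.

## Evaluation metrics

- **Marker correlation**: mean over marker gene/protein pairs of the average
  of Pearson and Spearman correlation between denoised gene expression and
  CLR-normalized protein abundance (CLR per cell:
  `log1p(x) - mean(log1p(x))`). Zero-variance columns score 0 with a
  warning.
- **Latent classifier F1**: macro F1 of scikit-learn logistic regression on
  the latent coordinates.
- **Clustering**: k-means (`n_init = 10`) with k equal to the number of true
  types; ARI, NMI, silhouette rescaled to [0, 1] by `(s + 1) / 2`, and
  matched cluster accuracy via the Hungarian algorithm on the contingency
  table. "Pooled" is the mean of the four.
- **Marginal log-likelihood**: the importance-weighted bound above,
  averaged over cells.

All metrics are reported separately for a seeded train/test split with
`|train| = round(0.9 * N)`.

## Limitations

- The autodiff engine is minimal and CPU-only; training scales to the tens
  of thousands of cells, not millions.
- Gating assumes each protein is bimodal; proteins with a single mode are
  rejected at fit time rather than silently mis-gated.
- The Bernoulli label likelihood treats gated probabilities as soft targets;
  calibration of the gate is inherited, not corrected.
- Early stopping uses the total loss on a held-out fraction, so `gamma`
  indirectly affects the stopping point; comparisons in this package fix
  `max_epochs` and disable patience where exactness matters.
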