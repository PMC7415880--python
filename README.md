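# citevae

Semisupervised zero-inflated negative binomial (ZINB) autoencoding of
single-cell RNA-seq counts, with CITE-seq surface-protein measurements as
auxiliary supervision.

## The idea

Single-cell RNA-seq counts are sparse, overdispersed and zero-inflated: a
gene can read zero either because it is off or because the assay dropped it.
A variational autoencoder with a ZINB observation model handles the count
noise, but its latent space is shaped only by the transcriptome.

CITE-seq experiments also measure a small panel of surface proteins (ADT
counts) per cell. Protein abundance is a far cleaner readout of cell state
than the mRNA of the same marker. `citevae` uses it as *soft supervision*:

1. **Gating.** Each protein's distribution is fit with a two-component
   mixture (EM, deterministic quantile initialization). The posterior
   probability of the high ("on") component converts raw ADT counts into a
   probabilistic label in [0, 1] per cell per protein — no manual
   thresholds, and scale differences between proteins are removed.
2. **Semisupervised objective.** A VAE is trained on the gene counts with a
   ZINB decoder. A second decoder head predicts the gated protein labels
   from the same latent code. The training loss is the negative evidence
   lower bound plus `gamma` times the label negative log-likelihood,
   averaged over labeled cells. `gamma = 0` recovers a plain unsupervised
   ZINB VAE — bitwise, under a fixed seed.

The supervised head pulls the latent space toward protein-defined cell
states. Downstream, the model denoises ("imputes") expression, embeds cells,
predicts protein levels from RNA alone, and scores its own fit by an
importance-weighted marginal likelihood.

## Worked example

```python
import pandas as pd
import citevae as cv

# simulate a small CITE-seq-style dataset: 500 cells, 100 genes, 5 proteins
counts, proteins, types, pairs, _ = cv.simulate(cv.SimSpec(seed=0))

# gate each protein with a two-component mixture -> probabilistic labels
adt = proteins.to_frame()
labels = cv.ProteinGating().fit(adt).transform(adt)

# train the semisupervised model and an unsupervised control
fit = lambda g: cv.SemiSupervisedVAE(gamma=g, max_epochs=100, patience=None,
                                     seed=0).fit(counts.values,
                                                 labels if g else None)
semi, unsup = fit(20.0), fit(0.0)

clr = cv.clr_normalize(proteins).to_frame()
for name, model in [("semisupervised", semi), ("unsupervised", unsup)]:
    imputed = pd.DataFrame(model.impute(counts.values),
                           index=counts.cell_ids, columns=counts.gene_ids)
    rho, _ = cv.marker_correlation(imputed, clr, pairs)
    pooled = cv.clustering_score(model.transform(counts.values), types)["pooled"]
    print(f"{name:>14}: marker correlation {rho:.3f}, clustering score {pooled:.3f}")
```

Output (seconds on a laptop-class CPU):

```
semisupervised: marker correlation 0.691, clustering score 0.936
  unsupervised: marker correlation 0.560, clustering score 0.709
```

`marker_correlation` is the mean of Pearson and Spearman correlation between
each marker gene's denoised expression and its paired protein (CLR scale);
`clustering score` pools ARI, NMI, rescaled silhouette and matched cluster
accuracy of k-means on the latent space against the generating cell types.
The protein supervision improves both, on the same data, at the same budget.

## Command line

Every step is also a `citevae` subcommand operating on 10x-style
matrix-market triplets and CSV tables:

```bash
citevae simulate --seed 0 --out data/
citevae fit-gmm  --proteins data/proteins.csv --out gate/
citevae train    --counts data/counts --proteins data/proteins.csv \
                 --gamma 20 --out run/
citevae impute   --counts data/counts --model run/model.npz --out run/
citevae predict  --counts data/counts --model run/model.npz --out run/
citevae evaluate --counts data/counts --model run/model.npz \
                 --proteins data/proteins.csv --labels data/labels.csv \
                 --pairs data/pairs.csv --out run/eval/
citevae benchmark --counts data/counts --proteins data/proteins.csv \
                 --pairs data/pairs.csv --labels data/labels.csv --out bench/
```

`benchmark` corrupts a fixed fraction of count entries by binomial
downsampling and compares semisupervised, unsupervised, identity and oracle
models on the corrupted data. Each command writes a `manifest.json`
recording its inputs, parameters and seed.

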