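import numpy as np
import pandas as pd
import pytest

import citevae as cv


@pytest.fixture(scope="session")
def small_dataset():
    """Modest synthetic CITE-seq dataset shared across tests."""
    spec = cv.SimSpec(n_cells=200, n_genes=40, n_proteins=4, n_types=3,
                      marker_pairs=4, seed=11)
    counts, proteins, types, pairs, truth = cv.simulate(spec)
    return {"spec": spec, "counts": counts, "proteins": proteins,
            "types": types, "pairs": pairs, "truth": truth}


@pytest.fixture(scope="session")
def probabilized_labels(small_dataset):
    gate = cv.ProteinGating().fit(small_dataset["proteins"].to_frame())
    return gate.transform(small_dataset["proteins"].to_frame())


@pytest.fixture(scope="session")
def trained_model(small_dataset, probabilized_labels):
    """A quickly trained semisupervised model on the shared dataset."""
    model = cv.SemiSupervisedVAE(n_hidden_units=32, n_latent=8, gamma=20.0,
                                 max_epochs=80, patience=None, seed=7)
    model.fit(small_dataset["counts"].values, probabilized_labels)
    return model


@pytest.fixture()
def tiny_untrained():
    """Initialized but untrained model for smoke and purity checks."""
    return cv.SemiSupervisedVAE(n_hidden_units=8, n_latent=4, seed=0).initialize(
        n_genes=10, n_proteins=3, median_library=30.0)
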