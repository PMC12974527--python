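import numpy as np
import pandas as pd
import pytest

import protstab as ps


@pytest.fixture()
def small_decay_truth():
    """Hand-built kinetic ground truth: one 2 h half-life protein, one stable."""
    return pd.DataFrame({
        "protein_id": ["FAST", "STABLE"],
        "is_unstable": [True, False],
        "true_halflife": [2.0, np.inf],
        "true_A0": [1e6, 1e6],
    })


@pytest.fixture()
def noiseless_spec():
    return ps.DecaySimSpec(
        n_proteins=2, frac_unstable=0.5, timepoints=(0.0, 1.0, 2.0, 4.0),
        replicates_per_timepoint=1, noise_sd=0.0, channel_bias_sd=0.0, seed=0)


@pytest.fixture()
def tiny_corpus_spec():
    return ps.CorpusSimSpec(
        gene_names=("pdeH", "clpS", "rpoH"),
        degradation_terms=("degraded", "proteolysis", "unstable"),
        n_documents=10, n_planted_positive=3, seed=42)


@pytest.fixture()
def gene_dict(tiny_corpus_spec):
    return {g: f"UP_{g}" for g in tiny_corpus_spec.gene_names}
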