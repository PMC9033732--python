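import numpy as np
import pandas as pd
import pytest

from anchorcoex import CompendiumConfig, ExpressionCompendium, SampleMeta, simulate_compendium
from anchorcoex.examples import btr_meiosis_compendium


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def btr_compendium():
    """The published 2-anchor x 8-sample meiosis worked example."""
    return btr_meiosis_compendium()


@pytest.fixture
def default_synthetic():
    return simulate_compendium(CompendiumConfig(seed=11))


def make_compendium(values, sample_ids=None, gene_ids=None, group=None):
    """Small ad-hoc compendium from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n_samples)]
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    samples = [SampleMeta(s, "proj", "tissue", "stage", group or s) for s in sample_ids]
    return ExpressionCompendium(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        samples=samples,
    )
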