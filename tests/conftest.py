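import warnings

import numpy as np
import pytest

from cubgrowth import CubgrowthWarning, GeneRecord
from cubgrowth.codonstats import background_from_counts
from tests._oracle import ALL_FAMILY_CODONS, FAMILIES


def random_gene(rng, n_codons=100, gene_id="g", he=False, weight=1.0):
    """A random coding sequence built from degenerate-family codons."""
    codons = rng.choice(ALL_FAMILY_CODONS, size=n_codons)
    return GeneRecord(
        id=gene_id,
        sequence="".join(codons),
        is_highly_expressed=he,
        weight=weight,
    )


def random_background(rng, concentration=1.0):
    """A random family-normalized background with strictly positive counts."""
    counts = np.zeros(64, dtype=np.int64)
    from cubgrowth._genetic_code import codon_index

    for codons in FAMILIES.values():
        raw = rng.gamma(concentration, size=len(codons)) + 0.05
        scaled = np.maximum((raw * 1000).astype(np.int64), 1)
        for c, k in zip(codons, scaled):
            counts[codon_index(c)] = k
    return background_from_counts(counts, source="sample-wide")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _quiet_pipeline_warnings():
    """Pipeline warnings (HE < 10, trimming, ...) are expected in synthetic
    fixtures; tests that care assert them explicitly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CubgrowthWarning)
        yield
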