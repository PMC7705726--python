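import numpy as np
import pandas as pd
import pytest

from dimorph.model import ExpressionMatrix, GeneMeta, SampleMeta, SEXES, STAGES
from dimorph.normalization import normalize_tmm
from dimorph.synthetic import SyntheticSpec, generate


def make_matrix(values, gene_ids=None, chromosomes=None, sample_pairs=None, normalized=False):
    """Small ExpressionMatrix helper for hand-built test cases.

    ``sample_pairs`` is a list of (sex, stage); defaults to both sexes at
    the stages needed to cover the requested number of columns.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if sample_pairs is None:
        pairs = [(sex, stage) for sex in SEXES for stage in STAGES]
        sample_pairs = pairs[:n_samples]
    samples = [
        SampleMeta(sample_id=f"{sex[0].upper()}_{stage}", sex=sex, stage=stage)
        for sex, stage in sample_pairs
    ]
    if chromosomes is None:
        chromosomes = ["autosome"] * n_genes
    genes = [GeneMeta(g, c) for g, c in zip(gene_ids, chromosomes)]
    df = pd.DataFrame(values, index=gene_ids, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(values=df, samples=samples, genes=genes, normalized=normalized)


def full_design_matrix(log2_by_sex_stage, gene_ids=None, chromosomes=None, normalized=True):
    """Matrix with all 8 (sex, stage) columns from a dict of log2 vectors."""
    pairs = [(sex, stage) for sex in SEXES for stage in STAGES]
    cols = np.stack([2.0 ** np.asarray(log2_by_sex_stage[p], dtype=float) for p in pairs], axis=1)
    return make_matrix(cols, gene_ids=gene_ids, chromosomes=chromosomes,
                       sample_pairs=pairs, normalized=normalized)


@pytest.fixture(scope="session")
def default_bundle():
    """Default-condition synthetic dataset, generated once per session."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def default_normalized(default_bundle):
    normalized, factors = normalize_tmm(default_bundle.matrix)
    return normalized, factors
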