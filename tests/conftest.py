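import numpy as np
import pytest

from nqtl.matrixio import ExpressionMatrix, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_expression(rng, n_genes=10, n_samples=20, prefix="g"):
    return ExpressionMatrix(
        row_ids=[f"{prefix}{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=rng.standard_normal((n_genes, n_samples)),
    )


def make_genotypes(rng, n_snps=10, n_samples=20, coded=False):
    if coded:
        vals = rng.integers(0, 3, size=(n_snps, n_samples)).astype(float)
    else:
        vals = rng.standard_normal((n_snps, n_samples))
    return GenotypeMatrix(
        row_ids=[f"snp{i}" for i in range(n_snps)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=vals,
    )


@pytest.fixture
def expr(rng):
    return make_expression(rng)


@pytest.fixture
def genotypes(rng):
    return make_genotypes(rng)
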