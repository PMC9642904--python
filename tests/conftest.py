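import numpy as np
import pytest

from prismvote.io import GenotypeMatrix, VariantRecord


def make_genotypes(G, chrom="1"):
    """Wrap an integer count matrix in a GenotypeMatrix with stub metadata."""
    G = np.asarray(G, dtype=np.int8)
    samples = [f"S{i + 1}" for i in range(G.shape[0])]
    variants = [VariantRecord(chrom, j + 1, f"snp{j + 1}", "A", "C")
                for j in range(G.shape[1])]
    return GenotypeMatrix(samples=samples, variants=variants, G=G)


@pytest.fixture
def small_genotypes():
    """6 samples x 4 variants, minor-allele coded, no missing."""
    rng = np.random.default_rng(42)
    G = rng.binomial(2, 0.25, size=(6, 4))
    return make_genotypes(G)


@pytest.fixture
def two_pop_cohort():
    """A small two-population cohort with a heritable continuous trait."""
    from prismvote.simulate import simulate_mixed_cohort

    return simulate_mixed_cohort(
        P=300, n_pop1=150, n_pop2=150, n_admixed=0, fst=0.2,
        n_causal=90, effect_model="correlated", eta=0.3, h2=0.8, seed=7,
    )
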