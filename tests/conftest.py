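import numpy as np
import pytest

from locogwas.io import GenotypeMatrix, MarkerRecord


def make_panel(n, m, n_chrom=2, seed=0, maf_floor=0.1):
    """Random imputed biallelic panel in minor-allele coding."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_floor, 0.5, size=m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    freq = dosage.mean(axis=0) / 2.0
    flip = freq > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]
    per_chrom = m // n_chrom
    markers = [
        MarkerRecord(
            id=f"m{j}",
            chromosome=str(min(j // per_chrom, n_chrom - 1) + 1),
            position=1 + (j % per_chrom) * 1000,
        )
        for j in range(m)
    ]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)], markers=markers, dosage=dosage
    )


@pytest.fixture
def small_panel():
    return make_panel(10, 50, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
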