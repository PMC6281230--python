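import numpy as np
import pytest

from canipop.io import GenotypeDataset, MarkerMap


def toy_markers(m, chromosomes=1, spacing_bp=5000, chrom_labels=None):
    per = m // chromosomes
    chrom = np.repeat(
        chrom_labels or [str(c + 1) for c in range(chromosomes)], per
    ).astype(object)
    pos = np.tile(1 + spacing_bp * np.arange(per, dtype=np.int64), chromosomes)
    return MarkerMap(
        np.array([f"m{i}" for i in range(m)], dtype=object),
        chrom,
        pos,
        np.array(["A"] * m, dtype=object),
        np.array(["G"] * m, dtype=object),
    )


def toy_dataset(dosage, chromosomes=1, spacing_bp=5000, sample_ids=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    return GenotypeDataset(ids, toy_markers(m, chromosomes, spacing_bp), dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
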