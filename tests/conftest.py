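import numpy as np
import pytest

from vernaliza.genomics_io import GenotypeMatrix


def make_gm(dosages, chrom=None, pos=None, qual=None, sample_ids=None):
    """Small-matrix constructor with sensible metadata defaults."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_acc, n_sites = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_sites, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n_sites + 1) * 100),
        qual=np.array(qual if qual is not None else [30.0] * n_sites, dtype=float),
        sample_ids=np.array(
            sample_ids if sample_ids is not None else [f"s{i}" for i in range(n_acc)],
            dtype=object,
        ),
    )


@pytest.fixture
def gm_builder():
    return make_gm


def random_gm(rng, n_acc=10, n_sites=10, missing_rate=0.0):
    d = rng.integers(0, 3, size=(n_acc, n_sites)).astype(np.int8)
    if missing_rate > 0:
        d[rng.random((n_acc, n_sites)) < missing_rate] = -1
    return make_gm(
        d,
        qual=rng.uniform(10, 60, n_sites).round(2),
        pos=np.sort(rng.choice(np.arange(1, 100000), size=n_sites, replace=False)),
    )
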