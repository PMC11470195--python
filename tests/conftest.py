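import numpy as np
import pandas as pd
import pytest

from riverpopgen.dataset import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def tiny_dataset():
    """3 samples x 4 loci with one missing call and site metadata."""
    dosages = np.array([
        [0, 1, 2, 1],
        [1, 1, 0, -1],
        [2, 0, 1, 0],
    ])
    ds = GenotypeDataset(
        dosages=dosages,
        sample_ids=np.array(["i1", "i2", "i3"], dtype=object),
        locus_meta=pd.DataFrame({
            "locus_id": ["L1", "L2", "L3", "L4"],
            "tag_id": ["T1", "T1", "T2", "T3"],
            "chrom": ["1", "1", "2", None],
            "pos": [100, 40_000, 5_000, None],
            "mean_depth": [10.0, 20.0, 3.0, 30.0],
            "reproducibility": [1.0, 0.99, 1.0, 0.90],
        }),
    )
    ds.sample_meta["site"] = ["S1", "S1", "S2"]
    ds.sample_meta["river_km"] = [0.0, 0.0, 12.5]
    ds.sample_meta["capture_year"] = [2021, 2021, 2022]
    return ds


def hwe_dataset(freqs, n, rng, sample_prefix="s"):
    """HWE genotypes at the given allele frequencies (no missing data)."""
    freqs = np.asarray(freqs, dtype=float)
    d = (rng.random((n, len(freqs))) < freqs).astype(np.int8) + \
        (rng.random((n, len(freqs))) < freqs).astype(np.int8)
    return GenotypeDataset(
        dosages=d,
        sample_ids=np.array([f"{sample_prefix}{i}" for i in range(n)],
                            dtype=object),
        locus_meta=None,
    )
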