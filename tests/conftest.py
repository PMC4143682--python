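import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regassoc.io import GenotypeMatrix
from regassoc.pedigree import PedigreeSet, Person

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_gm(dosages, samples=None, chrom="3", positions=None, mafs=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix straight from a dosage array (rows = persons)."""
    D = np.asarray(dosages, dtype=float)
    n, m = D.shape
    samples = samples or [f"s{i}" for i in range(n)]
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "vid": [f"{chrom}-{p}" for p in positions],
            "ref": "A",
            "alt": "C",
            "maf": mafs if mafs is not None else np.zeros(m),
        }
    )
    gm = GenotypeMatrix(samples=list(samples), variants=variants, dosages=D)
    if mafs is None:
        gm.recompute_maf()
    return gm


@pytest.fixture
def trio_pedset():
    """Single trio: father f, mother m, child c."""
    return PedigreeSet(
        [
            Person("fam1", "f", sex=1),
            Person("fam1", "m", sex=2),
            Person("fam1", "c", father="f", mother="m", sex=1),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
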