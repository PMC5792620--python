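import numpy as np
import pandas as pd
import pytest

from museum_popgen.genotypes import GenotypeMatrix


def make_gm(genotypes, depths=None, quals=None, sample_ids=None,
            refs=None, alts=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a genotype array (rows = samples)."""
    gt = np.asarray(genotypes, dtype=np.int8)
    n, m = gt.shape
    if depths is None:
        depths = np.where(gt == -1, 0, 20)
    if quals is None:
        quals = np.full(m, 100.0)
    loci = pd.DataFrame(
        {
            "chrom": [f"locus{j:04d}" for j in range(m)],
            "pos": np.ones(m, dtype=int),
            "ref": refs if refs is not None else ["A"] * m,
            "alt": alts if alts is not None else ["T"] * m,
            "qual": np.asarray(quals, dtype=float),
        }
    )
    ids = sample_ids if sample_ids is not None else [f"s{i:02d}" for i in range(n)]
    return GenotypeMatrix(ids, loci, gt, np.asarray(depths, dtype=np.int32))


def make_popmap(assignments) -> pd.DataFrame:
    """assignments: list of (sample_id, population, location, year)."""
    return pd.DataFrame(
        assignments, columns=["sample_id", "population", "location", "year"]
    )


def two_pop_map(gm, n_a, pop_a="A", pop_b="B", year_a=1940, year_b=2005):
    rows = []
    for i, sid in enumerate(gm.sample_ids):
        if i < n_a:
            rows.append((sid, pop_a, pop_a, year_a))
        else:
            rows.append((sid, pop_b, pop_b, year_b))
    return make_popmap(rows)


@pytest.fixture(scope="session")
def hyrad_like():
    """One hyrad-like synthetic dataset, shared across tests."""
    from museum_popgen import hyrad_like_dataset

    return hyrad_like_dataset(seed=20240901)
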