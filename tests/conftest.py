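import numpy as np
import pytest

import loopshift as ls


@pytest.fixture(scope="session")
def planted_maps():
    """Two-replicate, two-condition contact maps with planted loops (shared)."""
    maps, truth = ls.simulate_contact_maps(
        n_bins=800,
        loops={"n": 15, "enrichment": 3.0, "min_dist": 15, "max_dist": 120},
        dispersion=0.05,
        replicates=2,
        conditions=2,
        condition_loop_factor=[3.0] * 5 + [1.0] * 10,
        max_dist=160,
        seed=42,
    )
    return maps, truth


@pytest.fixture(scope="session")
def normalized_pair(planted_maps):
    maps, truth = planted_maps
    out = []
    for rep in (0, 1):
        bias, norm = ls.ipf_normalize(maps[(0, rep)])
        out.append((bias, norm, ls.fit_expected(norm)))
    return out


def uniform_normalized(n, value=1.0, bin_size=10_000):
    """Dense constant normalized matrix helper used by topology tests."""
    from loopshift.contact import BiasVector, NormalizedMatrix

    rows, cols = np.triu_indices(n)
    return NormalizedMatrix(
        chromosome="chrT",
        bin_size=bin_size,
        n_bins=n,
        rows=rows,
        cols=cols,
        vals=np.full(rows.size, float(value)),
        bias=BiasVector(np.ones(n)),
    )


def matrix_to_normalized(M, bin_size=10_000):
    from loopshift.contact import BiasVector, NormalizedMatrix

    n = M.shape[0]
    rows, cols = np.triu_indices(n)
    return NormalizedMatrix(
        chromosome="chrT",
        bin_size=bin_size,
        n_bins=n,
        rows=rows,
        cols=cols,
        vals=M[rows, cols].astype(float),
        bias=BiasVector(np.ones(n)),
    )
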