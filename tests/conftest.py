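import numpy as np
import pandas as pd
import pytest

from privar.core_io import MISSING, UNKNOWN_DEPTH, VariantTable


def build_table(genotypes, alleles=None, depths=None, samples=None,
                chroms=None, positions=None, site_kind=None) -> VariantTable:
    """Construct a VariantTable from a nested genotype list.

    ``genotypes[s][n]`` is an (a, b) pair or None for missing.
    """
    S = len(genotypes)
    N = len(genotypes[0])
    g = np.full((S, N, 2), MISSING, dtype=np.int16)
    for s in range(S):
        for n in range(N):
            call = genotypes[s][n]
            if call is not None:
                g[s, n] = sorted(call)
    alleles = alleles or [("A", "G")] * S
    if depths is None:
        d = np.full((S, N), UNKNOWN_DEPTH, dtype=np.int32)
    else:
        d = np.asarray(depths, dtype=np.int32)
    if site_kind is None:
        site_kind = np.array(
            [any(len(a) != len(row[0]) for a in row[1:]) for row in alleles])
    table = VariantTable(
        chroms=np.array(chroms or ["chr1"] * S, dtype=object),
        positions=np.array(positions or range(100, 100 + 10 * S, 10),
                           dtype=np.int64),
        alleles=list(alleles),
        genotypes=g,
        depths=d,
        samples=list(samples or [f"s{i}" for i in range(N)]),
        site_kind=np.asarray(site_kind, dtype=bool),
    )
    table.validate()
    return table


def make_meta(samples, statuses=None, regions=None) -> pd.DataFrame:
    n = len(samples)
    return pd.DataFrame({
        "sample": list(samples),
        "status": list(statuses or ["landrace"] * n),
        "region": list(regions or ["R1"] * n),
        "country": ["XX"] * n,
    })


@pytest.fixture
def table_builder():
    return build_table


@pytest.fixture
def meta_builder():
    return make_meta
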