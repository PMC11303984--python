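"""Identity-by-state duplicate detection and pruning.

Duplicated accessions (re-sequenced or re-deposited germplasm) have no true
private variants, so they must be removed before per-sample uniqueness
statistics.  Similarity is plain flat-weighted IBS: the fraction of allele
slots shared by state, averaged over mutually non-missing sites, with every
comparable site weighing 1 (no allele-frequency weighting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, VariantTable

log = logging.getLogger(__name__)

DEFAULT_IBS_THRESHOLD = 0.985

#: sentinel for pairs with zero comparable sites
UNDEFINED = np.nan


@dataclass
class IBSMatrix:
    """Symmetric IBS similarity matrix with comparable-site counts."""

    samples: list
    values: np.ndarray          # (N, N) in [0,1]; NaN where undefined
    comparable_sites: np.ndarray  # (N, N) int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples,
                            columns=self.samples)


def ibs_matrix(table: VariantTable) -> IBSMatrix:
    """Pairwise IBS similarity over mutually non-missing sites.

    The per-site share for two diploid genotypes is the multiset overlap of
    their allele pairs divided by 2, i.e. 1 for identical genotypes, 0.5
    when exactly one allele slot matches under the best order-free pairing,
    0 otherwise.  Pairs with no comparable site get NaN and a warning.
    """
    if table.n_samples < 2:
        raise ValueError("IBS requires at least 2 samples")
    g = table.genotypes  # (S, N, 2), pairs stored sorted
    N = table.n_samples
    valid = g[:, :, 0] != MISSING
    a0, a1 = g[:, :, 0], g[:, :, 1]

    values = np.ones((N, N))
    counts = np.zeros((N, N), dtype=np.int64)
    counts[np.diag_indices(N)] = valid.sum(axis=0)
    for i in range(N):
        vi = valid[:, i]
        x0, x1 = a0[:, i], a1[:, i]
        both = vi[:, None] & valid[:, i + 1:]
        y0, y1 = a0[:, i + 1:], a1[:, i + 1:]
        # multiset overlap of sorted pairs = best of the two pairings
        straight = (x0[:, None] == y0).astype(np.int8) + (x1[:, None] == y1)
        crossed = (x0[:, None] == y1).astype(np.int8) + (x1[:, None] == y0)
        share = np.maximum(straight, crossed) * both
        n_comp = both.sum(axis=0)
        with np.errstate(invalid="ignore"):
            sim = share.sum(axis=0, dtype=np.int64) / (2.0 * n_comp)
        values[i, i + 1:] = values[i + 1:, i] = sim
        counts[i, i + 1:] = counts[i + 1:, i] = n_comp

    n_undef = int(np.isnan(values[np.triu_indices(N, 1)]).sum())
    if n_undef:
        log.warning("%d sample pairs share no comparable sites; "
                    "their IBS is undefined", n_undef)
    return IBSMatrix(list(table.samples), values, counts)


def find_duplicate_groups(matrix: IBSMatrix,
                          threshold: float = DEFAULT_IBS_THRESHOLD) -> list:
    """Connected components of the IBS > threshold graph (size ≥ 2).

    Transitive: A~B and B~C group {A,B,C} even if IBS(A,C) ≤ threshold.
    Undefined (NaN) pairs never contribute edges.
    """
    N = len(matrix.samples)
    with np.errstate(invalid="ignore"):
        adj = matrix.values > threshold
    np.fill_diagonal(adj, False)
    # union-find over the small adjacency graph
    parent = list(range(N))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.nonzero(np.triu(adj, 1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri
    comps: dict[int, list] = {}
    for i in range(N):
        comps.setdefault(find(i), []).append(matrix.samples[i])
    return sorted((sorted(c) for c in comps.values() if len(c) >= 2),
                  key=lambda c: c[0])


def prune_duplicates(groups: list, meta: pd.DataFrame) -> tuple[list, list]:
    """Per duplicate group keep the sample with the lowest missingness.

    Ties break to the lexicographically smallest id.  Returns
    (retained ids over all samples in meta, dropped ids).
    """
    if "missingness" not in meta.columns:
        raise ValueError("meta lacks a missingness column; "
                         "use attach_missingness first")
    miss = meta.set_index("sample")["missingness"]
    dropped: list = []
    for group in groups:
        unknown = [s for s in group if s not in miss.index or pd.isna(miss[s])]
        if unknown:
            raise ValueError(f"missingness unknown for {unknown}")
        keep = min(group, key=lambda s: (miss[s], s))
        dropped.extend(s for s in group if s != keep)
    retained = [s for s in meta["sample"] if s not in set(dropped)]
    return retained, dropped


def duplicate_report(groups: list, dropped: list) -> pd.DataFrame:
    """Long-form TSV-ready table: group_id, sample, retained."""
    rows = [
        {"group_id": gi, "sample": s, "retained": "no" if s in set(dropped) else "yes"}
        for gi, group in enumerate(groups, 1)
        for s in group
    ]
    return pd.DataFrame(rows, columns=["group_id", "sample", "retained"])
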