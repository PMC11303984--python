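"""Diversity estimators for aligned sequences and haplotype counts.

All sequence-based estimators use pairwise deletion: an alignment column is
included when at least two sequences carry an unambiguous A/C/G/T there
(gaps and IUPAC ambiguity codes count as missing), and per-site quantities
are averaged over the sequences valid at that site.  Per-site normalisation
divides by the number of included columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

MIN_VALID_PER_SITE = 2  # a column needs >=2 unambiguous bases to be scored


def _state_matrix(seqs) -> np.ndarray:
    """Upper-case character matrix; non-ACGT become ``N`` (missing)."""
    seqs = [str(s).upper() for s in seqs]
    if len(set(map(len, seqs))) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(s) for s in seqs], dtype="U1")
    arr[~np.isin(arr, list(VALID_BASES))] = "N"
    return arr


def _site_inclusion(arr: np.ndarray) -> np.ndarray:
    return (arr != "N").sum(axis=0) >= MIN_VALID_PER_SITE


def nucleotide_diversity_pi(seqs) -> float:
    """Per-site nucleotide diversity π with pairwise deletion.

    Each included column contributes the mean pairwise difference among its
    valid sequences; π is the sum of those contributions divided by the
    number of included columns.  NaN for fewer than two sequences or no
    included column.
    """
    if len(seqs) < 2:
        return float("nan")
    arr = _state_matrix(seqs)
    include = _site_inclusion(arr)
    if not include.any():
        return float("nan")
    total = 0.0
    for col in arr[:, include].T:
        states, counts = np.unique(col[col != "N"], return_counts=True)
        n = counts.sum()
        same = sum(comb(int(c), 2) for c in counts)
        total += 1.0 - same / comb(int(n), 2)
    return total / int(include.sum())


def segregating_sites(seqs) -> tuple[int, int]:
    """(S, L): segregating and included column counts under pairwise deletion."""
    arr = _state_matrix(seqs)
    include = _site_inclusion(arr)
    L = int(include.sum())
    S = 0
    for col in arr[:, include].T:
        if len(np.unique(col[col != "N"])) >= 2:
            S += 1
    return S, L


def watterson_theta(seqs) -> float:
    """Per-site Watterson's Theta, ``S / (a_{n-1} L)``.

    ``n`` is the number of sequences in the group (not per-site valid
    counts), ``a_{n-1}`` the harmonic number, ``L`` the included column
    count.  NaN for n < 2 or L = 0.
    """
    n = len(seqs)
    if n < 2:
        return float("nan")
    S, L = segregating_sites(seqs)
    if L == 0:
        return float("nan")
    a = sum(1.0 / i for i in range(1, n))
    return S / (a * L)


def haplotype_diversity(counts) -> float:
    """Gene (haplotype) diversity ``H = N/(N-1) (1 - sum x_i^2)``.

    ``counts`` maps haplotype label to occurrence count (or is an iterable
    of counts); ``x_i`` are relative frequencies.  NaN for N < 2.
    """
    vals = np.asarray(list(counts.values()) if hasattr(counts, "values")
                      else list(counts), dtype=float)
    if (vals < 0).any() or not ((vals == np.floor(vals)).all()):
        raise ValueError("counts must be non-negative integers")
    N = vals.sum()
    if N < 2:
        return float("nan")
    x = vals / N
    return float(N / (N - 1) * (1.0 - (x ** 2).sum()))


def allelic_richness(counts, g: int) -> float:
    """Rarefied allelic richness A(g): expected distinct alleles in a
    size-``g`` subsample drawn without replacement.

    ``A(g) = sum_a [1 - C(N - N_a, g) / C(N, g)]`` with per-allele counts
    ``N_a`` and total ``N``; each haplotype counts as one allele.
    """
    vals = [int(v) for v in (counts.values() if hasattr(counts, "values")
                             else counts) if v > 0]
    N = sum(vals)
    if not (1 <= g <= N):
        raise ValueError(f"rarefaction size g={g} out of range [1, {N}]")
    denom = comb(N, g)
    return float(sum(1.0 - comb(N - na, g) / denom for na in vals))


def watterson_theta_genotypes(table, sample_ids) -> float:
    """Per-site Watterson's Theta from a diploid genotype matrix subset.

    S counts sites with >= 2 distinct alleles among the subset's
    non-missing calls; n is the number of allele copies (2 per sample); L
    is the total site count of the table.
    """
    import numpy as np  # local: keeps the sequence API numpy-free at import

    idx = {s: i for i, s in enumerate(table.samples)}
    cols = [idx[s] for s in sample_ids]
    if len(cols) < 2:
        return float("nan")
    g = table.genotypes[:, cols, :].reshape(table.n_sites, -1)
    seg = np.zeros(table.n_sites, dtype=bool)
    a_max = max(len(al) for al in table.alleles)
    present = [(g == a).any(axis=1) for a in range(a_max)]
    for a in range(a_max):
        for b in range(a + 1, a_max):
            seg |= present[a] & present[b]
    a_n = sum(1.0 / i for i in range(1, 2 * len(cols)))
    return float(seg.sum() / (a_n * table.n_sites))


@dataclass
class DiversityResult:
    group: str
    n: int
    segregating: int
    pi: float
    theta: float
    haplotype_diversity: float
    allelic_richness: float
    rarefaction_g: int


def group_diversity(seqs_by_group: dict, haplotype_by_sample: dict | None = None,
                    rarefaction_g: int | None = None) -> pd.DataFrame:
    """Per-group N, S, π, Theta, H and A(g) table.

    ``seqs_by_group`` maps group label to {sample id: sequence}.  Haplotype
    labels default to the sequence strings themselves unless
    ``haplotype_by_sample`` provides explicit assignments.  The default
    rarefaction size is the smallest group's N, so richness is comparable
    across unequal group sizes.
    """
    g = rarefaction_g or min(len(v) for v in seqs_by_group.values())
    rows = []
    for group, members in seqs_by_group.items():
        seqs = list(members.values())
        if haplotype_by_sample is None:
            labels = seqs
        else:
            labels = [haplotype_by_sample[s] for s in members]
        counts = pd.Series(labels).value_counts().to_dict()
        S, _L = segregating_sites(seqs) if len(seqs) >= 2 else (0, 0)
        rows.append(DiversityResult(
            group=group,
            n=len(seqs),
            segregating=S,
            pi=nucleotide_diversity_pi(seqs),
            theta=watterson_theta(seqs),
            haplotype_diversity=haplotype_diversity(counts),
            allelic_richness=allelic_richness(counts, min(g, len(seqs))),
            rarefaction_g=min(g, len(seqs)),
        ).__dict__)
    return pd.DataFrame(rows)
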