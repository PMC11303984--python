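"""Group-level variant partitioning and domestication scoring.

Operations comparing the wild, landrace and cultivar gene pools: which
variable positions each group carries (and how much wild diversity survived
domestication), whether group-specific SNPs cluster physically along
chromosomes, which sites carry near-fixed domestication alleles, and a
genotype PCA for overall structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DOMESTICATED_STATUSES, MISSING, VariantTable

VENN_GROUPS = ("cultivar", "landrace", "wild")


# ---------------------------------------------------------------------------
# variable-position partition
# ---------------------------------------------------------------------------


@dataclass
class VennPartition:
    sites_by_group: dict          # group -> set of site indices
    region_counts: dict           # frozenset of groups -> count
    wild_carryover: float         # fraction of wild-variable sites also
                                  # variable in landraces or cultivars

    def to_frame(self) -> pd.DataFrame:
        rows = [{"groups": "&".join(sorted(k)), "count": v}
                for k, v in sorted(self.region_counts.items(),
                                   key=lambda kv: (len(kv[0]), sorted(kv[0])))]
        return pd.DataFrame(rows)


def _variable_mask(table: VariantTable, sample_idx) -> np.ndarray:
    """Per-site: >= 2 distinct alleles among the subset's non-missing calls."""
    g = table.genotypes[:, sample_idx, :]
    S = table.n_sites
    out = np.zeros(S, dtype=bool)
    flat = g.reshape(S, -1)
    for s in range(S):
        alleles = flat[s][flat[s] != MISSING]
        out[s] = len(np.unique(alleles)) >= 2
    return out


def venn_partition(table: VariantTable, meta: pd.DataFrame) -> VennPartition:
    """Partition variable positions among cultivars, landraces and wild.

    A site is "variable in a group" when its non-missing calls in that
    group carry at least two distinct alleles (a heterozygote carries
    both).  Reports all seven intersection-region counts and the fraction
    of wild-variable sites also variable in the domesticated union.
    """
    idx = {s: i for i, s in enumerate(table.samples)}
    sites_by_group = {}
    for group in VENN_GROUPS:
        members = meta.loc[meta["status"] == group, "sample"]
        cols = [idx[s] for s in members if s in idx]
        if not cols:
            raise ValueError(f"group {group!r} has no samples in the table")
        sites_by_group[group] = set(
            np.flatnonzero(_variable_mask(table, cols)).tolist())

    region_counts = {}
    for r in range(1, 8):
        combo = frozenset(g for b, g in enumerate(VENN_GROUPS) if r >> b & 1)
        inside = set.intersection(*(sites_by_group[g] for g in combo))
        outside = set.union(*(sites_by_group[g] for g in
                              set(VENN_GROUPS) - combo), set())
        region_counts[combo] = len(inside - outside)

    wild = sites_by_group["wild"]
    dom = sites_by_group["cultivar"] | sites_by_group["landrace"]
    carry = len(wild & dom) / len(wild) if wild else float("nan")
    return VennPartition(sites_by_group, region_counts, carry)


# ---------------------------------------------------------------------------
# physical clustering of group-specific SNPs
# ---------------------------------------------------------------------------


@dataclass
class ClusteringTest:
    observed: float
    null: np.ndarray
    p_value: float
    n_draws: int
    seed: int
    statistic: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "observed": self.observed, "null_mean": float(self.null.mean()),
            "null_sd": float(self.null.std(ddof=1)),
            "p_value": self.p_value, "n_draws": self.n_draws,
            "seed": self.seed, "statistic": self.statistic,
        }])


def _spacing_statistic(chrom_rank: np.ndarray, positions: np.ndarray,
                       subset: np.ndarray, statistic: str) -> float:
    """Mean nearest-neighbour (or adjacent-gap) distance of a site subset,
    chromosome by chromosome; chromosomes with < 2 subset sites contribute
    nothing."""
    total, count = 0.0, 0
    cr = chrom_rank[subset]
    pos = positions[subset]
    for c in np.unique(cr):
        p = np.sort(pos[cr == c])
        if len(p) < 2:
            continue
        gaps = np.diff(p)
        if statistic == "nearest":
            nn = np.empty(len(p))
            nn[0], nn[-1] = gaps[0], gaps[-1]
            if len(p) > 2:
                nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
            total += nn.sum()
            count += len(p)
        else:  # adjacent-gap mean
            total += gaps.sum()
            count += len(gaps)
    if count == 0:
        raise ValueError("no chromosome carries >= 2 subset sites")
    return total / count


def specific_snp_clustering(table: VariantTable, specific_sites,
                            n_draws: int = 999, seed: int = 0,
                            statistic: str = "nearest",
                            variable_sites=None) -> ClusteringTest:
    """Permutation test: are the given sites physically clustered?

    The observed statistic is the mean per-chromosome nearest-neighbour
    base-pair distance among ``specific_sites`` (site indices); the null
    re-draws ``n_draws`` uniform subsets of the same size from all variable
    sites (or ``variable_sites`` if given).  The empirical p-value is
    ``(1 + #{null <= observed}) / (n_draws + 1)`` — small when the specific
    sites sit closer together than random subsets.
    """
    specific = np.asarray(sorted(set(int(s) for s in specific_sites)))
    if len(specific) < 2:
        raise ValueError("need >= 2 specific sites")
    if variable_sites is None:
        pool = np.flatnonzero(
            _variable_mask(table, list(range(table.n_samples))))
    else:
        pool = np.asarray(sorted(set(int(s) for s in variable_sites)))
    if not set(specific).issubset(set(pool.tolist())):
        raise ValueError("specific sites must be a subset of variable sites")

    chrom_order = {c: i for i, c in enumerate(pd.unique(table.chroms))}
    chrom_rank = np.array([chrom_order[c] for c in table.chroms])
    observed = _spacing_statistic(chrom_rank, table.positions, specific,
                                  statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    for i in range(n_draws):
        draw = rng.choice(pool, size=len(specific), replace=False)
        null[i] = _spacing_statistic(chrom_rank, table.positions, draw,
                                     statistic)
    p = (1.0 + np.count_nonzero(null <= observed)) / (n_draws + 1.0)
    return ClusteringTest(observed=float(observed), null=null,
                          p_value=float(p), n_draws=n_draws, seed=seed,
                          statistic=statistic)


# ---------------------------------------------------------------------------
# domestication-allele scoring
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticSiteSet:
    sites: np.ndarray        # site indices
    alleles: np.ndarray      # domesticated-variant allele index per site
    hi: float
    lo: float

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self, table: VariantTable) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": table.chroms[self.sites],
            "pos": table.positions[self.sites],
            "allele_index": self.alleles,
            "allele": [table.alleles[s][a]
                       for s, a in zip(self.sites, self.alleles)],
        })


def _group_allele_freqs(table: VariantTable, sample_idx) -> np.ndarray:
    """(S, A_max) allele frequencies over non-missing calls of a subset."""
    g = table.genotypes[:, sample_idx, :]
    S = table.n_sites
    a_max = max(len(a) for a in table.alleles)
    freqs = np.zeros((S, a_max))
    valid = (g != MISSING)
    totals = valid.sum(axis=(1, 2))
    for a in range(a_max):
        counts = (g == a).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, a] = np.where(totals > 0, counts / np.maximum(totals, 1),
                                   np.nan)
    return freqs


def diagnostic_sites(table: VariantTable, meta: pd.DataFrame,
                     hi: float = 0.95, lo: float = 0.25) -> DiagnosticSiteSet:
    """Sites near-fixed in domesticated barley but rare in wild barley.

    An allele qualifies when its frequency over non-missing domesticated
    calls is strictly > ``hi`` and over wild calls strictly < ``lo``
    (either allele of a site may qualify, reference included).  Samples
    flagged hybrid/feral — and the ancient specimens being scored — belong
    to neither frequency group.
    """
    idx = {s: i for i, s in enumerate(table.samples)}
    dom = [idx[s] for s in meta.loc[
        meta["status"].isin(DOMESTICATED_STATUSES), "sample"] if s in idx]
    wild = [idx[s] for s in meta.loc[meta["status"] == "wild", "sample"]
            if s in idx]
    if not dom or not wild:
        raise ValueError("both wild and domesticated groups must be non-empty")
    f_dom = _group_allele_freqs(table, dom)
    f_wild = _group_allele_freqs(table, wild)
    with np.errstate(invalid="ignore"):
        qualifies = (f_dom > hi) & (f_wild < lo)
    sites, alleles = np.nonzero(qualifies)
    # at most one allele can exceed hi > 0.5 per site
    return DiagnosticSiteSet(sites=sites, alleles=alleles, hi=hi, lo=lo)


def domestication_score(table: VariantTable, sample: str,
                        sites: DiagnosticSiteSet,
                        homozygous_only: bool = False) -> float:
    """Fraction of informative diagnostic sites carrying the domesticated
    variant in the given sample.

    A site is informative when the sample's call there is non-missing;
    carrying means >= 1 copy of the domesticated allele (both copies with
    ``homozygous_only``).  NaN when no diagnostic site is informative.
    """
    j = table.samples.index(sample)
    g = table.genotypes[sites.sites, j, :]       # (D, 2)
    informative = g[:, 0] != MISSING
    if not informative.any():
        return float("nan")
    hits = (g == sites.alleles[:, None])
    carries = hits.all(axis=1) if homozygous_only else hits.any(axis=1)
    return float(carries[informative].sum() / informative.sum())


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------


def genotype_pca(table: VariantTable, k: int = 2,
                 patterson_scaling: bool = True
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of alternate-allele dosages.

    Genotypes are encoded 0/1/2 as the dosage of the most frequent
    non-reference allele (multistate sites collapse to that allele),
    columns are mean-centred with missing entries imputed to the column
    mean, and by default scaled by ``sqrt(p(1-p))`` with ``p`` the dosage
    mean / 2.  Returns (coordinates frame indexed by sample, variance
    fractions of the top ``k`` components).
    """
    S, N = table.n_sites, table.n_samples
    if k > min(S, N):
        raise ValueError(f"k={k} exceeds min(n_samples, n_sites)")
    g = table.genotypes
    # most frequent non-reference allele per site
    a_max = max(len(a) for a in table.alleles)
    alt_counts = np.stack([(g == a).sum(axis=(1, 2)) for a in
                           range(1, a_max)], axis=1) if a_max > 1 else \
        np.zeros((S, 1), dtype=int)
    focal = alt_counts.argmax(axis=1) + 1
    dosage = (g == focal[:, None, None]).sum(axis=2).astype(float)  # (S, N)
    dosage[g[:, :, 0] == MISSING] = np.nan

    mean = np.nanmean(dosage, axis=1)
    mean = np.where(np.isnan(mean), 0.0, mean)
    centred = dosage - mean[:, None]
    centred[np.isnan(centred)] = 0.0
    if patterson_scaling:
        p = mean / 2.0
        scale = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
        centred = centred / scale[:, None]

    x = centred.T  # samples × sites
    u, svals, _vt = np.linalg.svd(x, full_matrices=False)
    total_var = (svals ** 2).sum()
    coords = u[:, :k] * svals[:k]
    var_frac = (svals[:k] ** 2) / total_var if total_var > 0 else \
        np.zeros(k)
    frame = pd.DataFrame(coords, index=pd.Index(table.samples, name="sample"),
                         columns=[f"PC{i + 1}" for i in range(k)])
    return frame, var_frac
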