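"""Per-sample private-variant (PV) statistics.

A private variant is an allele confined to a single individual of the sample
set, in homozygous state: a private doubleton SNP (the allele's two copies
both in one homozygous carrier) or a private homozygous indel.  Heterozygous
singletons are excluded — in a predominantly selfing species heterozygous
calls mostly reflect somatic mutation or mapping error, not standing
variation.  The per-sample PV proportion (PVs per non-missing genotype call)
measures the genetic uniqueness of an individual within the sample set and
is robust to the minimum-depth genotype threshold for samples with moderate
missingness, which is what makes it usable on ancient specimens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, VariantTable, mask_low_depth

log = logging.getLogger(__name__)

DEFAULT_MINDP_SET = (2, 3, 4, 5)

SINGLETON = "SINGLETON"
PRIVATE_DOUBLETON = "PRIVATE_DOUBLETON"
PRIVATE_INDEL = "PRIVATE_INDEL"
NON_PRIVATE = "NON_PRIVATE"


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_private_alleles(table: VariantTable) -> pd.DataFrame:
    """Classify every non-reference allele at every site.

    Returns a frame with columns ``site`` (row index into the table),
    ``allele`` (allele index ≥ 1), ``klass`` and ``carrier`` (sample id for
    singleton/private classes, else empty).  Occurrence counts are taken
    over non-missing genotypes only:

    * SINGLETON — one copy total (a single heterozygous carrier).
    * PRIVATE_DOUBLETON — two copies, both in one homozygous carrier, at a
      SNP site.
    * PRIVATE_INDEL — the same homozygous single-carrier pattern at an
      indel site.
    * NON_PRIVATE — anything else.

    Duplicate accessions should be pruned first; exact duplicate genotype
    columns trigger a warning because they zero each other's PVs.
    """
    _warn_exact_duplicates(table)
    g = table.genotypes
    S = table.n_sites
    n_alleles = np.fromiter((len(a) for a in table.alleles), int, count=S)
    max_alt = int(n_alleles.max()) - 1 if S else 0
    records = []
    for a in range(1, max_alt + 1):
        exists = n_alleles > a
        copies = (g == a).sum(axis=2, dtype=np.int16)      # (S, N)
        total = copies.sum(axis=1, dtype=np.int64)         # (S,)
        carriers = (copies > 0).sum(axis=1)                # (S,)
        single = exists & (total == 1)
        priv_hom = exists & (total == 2) & (carriers == 1)
        klass = np.full(S, NON_PRIVATE, dtype=object)
        klass[single] = SINGLETON
        klass[priv_hom & ~table.site_kind] = PRIVATE_DOUBLETON
        klass[priv_hom & table.site_kind] = PRIVATE_INDEL
        carrier_idx = np.where(single | priv_hom,
                               np.argmax(copies > 0, axis=1), -1)
        for s in np.flatnonzero(exists):
            records.append((s, a, klass[s],
                            table.samples[carrier_idx[s]]
                            if carrier_idx[s] >= 0 else ""))
    return pd.DataFrame(records, columns=["site", "allele", "klass", "carrier"])


def _per_sample_counts(table: VariantTable) -> pd.DataFrame:
    """Vectorized per-sample counts of singleton / PV alleles.

    Equivalent to aggregating :func:`classify_private_alleles` by carrier,
    but without materialising the per-allele frame (used inside the minDP
    sweep on large tables).
    """
    g = table.genotypes
    S, N = table.n_sites, table.n_samples
    n_alleles = np.fromiter((len(a) for a in table.alleles), int, count=S)
    max_alt = int(n_alleles.max()) - 1 if S else 0
    singles = np.zeros(N, dtype=np.int64)
    pd_snp = np.zeros(N, dtype=np.int64)
    pd_indel = np.zeros(N, dtype=np.int64)
    for a in range(1, max_alt + 1):
        exists = n_alleles > a
        copies = (g == a).sum(axis=2, dtype=np.int16)
        total = copies.sum(axis=1, dtype=np.int64)
        carriers = (copies > 0).sum(axis=1)
        single = exists & (total == 1)
        priv_hom = exists & (total == 2) & (carriers == 1)
        carrier_idx = np.argmax(copies > 0, axis=1)
        np.add.at(singles, carrier_idx[single], 1)
        np.add.at(pd_snp, carrier_idx[priv_hom & ~table.site_kind], 1)
        np.add.at(pd_indel, carrier_idx[priv_hom & table.site_kind], 1)
    valid = (g[:, :, 0] != MISSING).sum(axis=0, dtype=np.int64)
    frame = pd.DataFrame({
        "singletons": singles,
        "private_doubleton_snps": pd_snp,
        "private_hom_indels": pd_indel,
        "pv_total": pd_snp + pd_indel,
        "valid_calls": valid,
    }, index=pd.Index(table.samples, name="sample"))
    with np.errstate(invalid="ignore", divide="ignore"):
        frame["pv_percent"] = np.where(
            valid > 0, 100.0 * frame["pv_total"] / np.maximum(valid, 1),
            np.nan)
    return frame


# ---------------------------------------------------------------------------
# the minDP sweep
# ---------------------------------------------------------------------------


@dataclass
class PVReport:
    """Per-sample PV counts and proportions across minDP settings."""

    per_setting: dict            # minDP -> per-sample counts frame
    summary: pd.DataFrame        # mean/sd of pv_percent across settings
    min_dp_set: tuple

    def to_frame(self) -> pd.DataFrame:
        """Wide per-sample table (one count block per minDP + summary)."""
        blocks = [df.add_suffix(f"_minDP{dp}")
                  for dp, df in self.per_setting.items()]
        return pd.concat(blocks + [self.summary], axis=1)


def pv_proportions(table: VariantTable,
                   min_dp_set=DEFAULT_MINDP_SET,
                   strict_unknown: bool = False) -> PVReport:
    """Mask at each minDP, re-classify, and report PV proportions.

    Singleton/doubleton status is recomputed after each masking: each minDP
    defines its own genotype-calling regime.  The proportion denominator is
    the sample's non-missing calls over *all* retained sites at that
    masking, not only polymorphic ones.  Samples with zero valid calls get
    an undefined (NaN) proportion and are flagged.
    """
    per_setting = {}
    for dp in sorted(min_dp_set):
        masked = mask_low_depth(table, dp, strict_unknown=strict_unknown)
        per_setting[dp] = _per_sample_counts(masked)
    pct = pd.concat([df["pv_percent"] for df in per_setting.values()], axis=1)
    summary = pd.DataFrame({
        "pv_percent_mean": pct.mean(axis=1),
        "pv_percent_sd": pct.std(axis=1, ddof=1),
        "undefined": pct.isna().any(axis=1),
    })
    n_undef = int(summary["undefined"].sum())
    if n_undef:
        log.warning("%d samples have zero valid calls at some minDP; "
                    "their proportions are undefined", n_undef)
    return PVReport(per_setting, summary, tuple(sorted(min_dp_set)))


def _warn_exact_duplicates(table: VariantTable) -> None:
    cols = [table.genotypes[:, i].tobytes() for i in range(table.n_samples)]
    seen: dict[bytes, str] = {}
    for sid, key in zip(table.samples, cols):
        if key in seen and table.n_sites:
            log.warning("samples %s and %s have identical genotypes; "
                        "prune duplicates before PV analysis",
                        seen[key], sid)
        seen.setdefault(key, sid)


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the exact t transform.

    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.  Returns
    (nan, nan) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return (float("nan"), float("nan"))
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return (r, float(p))


def group_zscore(value: float, reference) -> float:
    """z of ``value`` against a reference group (sample sd, n-1).

    NaN when the reference sd is zero.
    """
    ref = np.asarray(reference, dtype=float)
    if len(ref) < 2:
        raise ValueError("reference group needs n >= 2")
    sd = ref.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((value - ref.mean()) / sd)


def thompson_tau_outliers(values, alpha: float = 0.05, ids=None) -> set:
    """Modified Thompson Tau outlier screen, iterated to convergence.

    At each step with n remaining points, the rejection threshold is
    ``tau = t_{alpha/2, n-2} (n-1) / (sqrt(n) sqrt(n-2+t^2))`` applied to the
    largest absolute deviation from the mean; the flagged point is removed
    and the test repeats.  Returns the flagged ids (indices by default).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Thompson Tau requires n >= 3")
    ids = list(range(len(values))) if ids is None else list(ids)
    remaining = list(range(len(values)))
    flagged: set = set()
    while len(remaining) >= 3:
        sub = values[remaining]
        s = sub.std(ddof=1)
        if s == 0:
            break
        n = len(sub)
        t = stats.t.ppf(1 - alpha / 2, df=n - 2)
        tau = t * (n - 1) / (np.sqrt(n) * np.sqrt(n - 2 + t * t))
        dev = np.abs(sub - sub.mean())
        k = int(np.argmax(dev))
        if dev[k] > tau * s:
            flagged.add(ids[remaining[k]])
            remaining.pop(k)
        else:
            break
    return flagged


def regional_summary(pv_percent: pd.Series, meta: pd.DataFrame,
                     theta_by_region: dict) -> tuple[pd.DataFrame, float, float]:
    """Regional mean PV proportions and their correlation with Theta.

    ``pv_percent`` is indexed by sample id (e.g. the ``pv_percent_mean``
    column of a :class:`PVReport` summary).  Only samples present in both
    the series and ``meta`` contribute.  Raises if a region lacks a Theta
    value or fewer than 3 regions remain.
    """
    merged = meta.set_index("sample").join(pv_percent.rename("pv_percent"),
                                           how="inner")
    merged = merged.dropna(subset=["pv_percent"])
    regions = merged.groupby("region")["pv_percent"].agg(["mean", "count"])
    missing = [r for r in regions.index if r not in theta_by_region]
    if missing:
        raise KeyError(f"regions absent from theta mapping: {missing}")
    regions["theta"] = [theta_by_region[r] for r in regions.index]
    if len(regions) < 3:
        raise ValueError("regional correlation requires >= 3 regions")
    r, p = correlate(regions["mean"].to_numpy(), regions["theta"].to_numpy())
    regions = regions.rename(columns={"mean": "pv_percent_mean",
                                      "count": "n_samples"})
    return regions.reset_index(), r, p
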