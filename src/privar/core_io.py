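"""Genotype-matrix I/O and site filtering.

The central container is :class:`VariantTable`, a sites × samples matrix of
unordered diploid genotype calls with per-genotype sequencing depth.  It is
built from a multi-sample VCF (4.x, plain or bgzipped) and a sample metadata
table, and is the input to duplicate pruning, private-variant statistics and
group-level partitioning.

Genotype calls are stored as allele-index pairs; ``-1`` marks a missing
allele.  Half-calls (``1/.``) are conservatively treated as fully missing.
Multiallelic records are kept as single multistate sites, never split.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  #: sentinel allele index for a missing call
UNKNOWN_DEPTH = -1  #: sentinel for absent DP

STATUSES = ("wild", "landrace", "cultivar", "ancient", "hybrid/feral")
#: statuses counted as the extant domesticated gene pool
DOMESTICATED_STATUSES = ("landrace", "cultivar")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be decoded."""


class SampleMismatchError(ValueError):
    """Raised when VCF sample ids do not match the metadata table."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Sites × samples diploid genotype matrix.

    Attributes
    ----------
    chroms : np.ndarray of str, shape (S,)
        Chromosome id per site.
    positions : np.ndarray of int, shape (S,)
        1-based coordinates, strictly increasing within a chromosome.
    alleles : list of tuple of str
        Per-site ordered allele strings, reference first.
    genotypes : np.ndarray of int16, shape (S, N, 2)
        Unordered allele-index pairs; ``MISSING`` (-1) in both slots for a
        missing call.  Pairs are stored sorted so equality is order-free.
    depths : np.ndarray of int32, shape (S, N)
        Per-genotype depth; ``UNKNOWN_DEPTH`` (-1) when the record carried
        no DP.
    samples : list of str
    site_kind : np.ndarray of bool, shape (S,)
        True where the site is an indel (any allele length differs from the
        reference allele length).
    """

    chroms: np.ndarray
    positions: np.ndarray
    alleles: list
    genotypes: np.ndarray
    depths: np.ndarray
    samples: list
    site_kind: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        S, N = self.n_sites, self.n_samples
        if self.genotypes.shape != (S, N, 2):
            raise ValueError("genotypes shape mismatch")
        if self.depths.shape != (S, N):
            raise ValueError("depths and genotypes have different dimensions")
        n_alleles = np.fromiter((len(a) for a in self.alleles), int, count=S)
        if S and (self.genotypes.max(axis=(1, 2)) >= n_alleles).any():
            raise ValueError("genotype allele index exceeds allele count")
        for chrom in pd.unique(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on {chrom}")

    # -- convenience views ---------------------------------------------------

    def missing_mask(self) -> np.ndarray:
        """(S, N) boolean mask of missing calls."""
        return self.genotypes[:, :, 0] == MISSING

    def het_mask(self) -> np.ndarray:
        """(S, N) boolean mask of heterozygous calls (two distinct alleles)."""
        g = self.genotypes
        return (g[:, :, 0] != g[:, :, 1]) & (g[:, :, 0] != MISSING)

    def sample_missingness(self) -> pd.Series:
        """Per-sample fraction of missing genotype calls."""
        frac = self.missing_mask().mean(axis=0) if self.n_sites else np.zeros(self.n_samples)
        return pd.Series(frac, index=self.samples, name="missingness")

    def take_sites(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        pos_idx = np.flatnonzero(idx) if idx.dtype == bool else idx
        return replace(
            self,
            chroms=self.chroms[pos_idx],
            positions=self.positions[pos_idx],
            alleles=[self.alleles[i] for i in pos_idx],
            genotypes=self.genotypes[pos_idx],
            depths=self.depths[pos_idx],
            site_kind=self.site_kind[pos_idx],
        )

    def take_samples(self, which) -> "VariantTable":
        """Subset samples by list of ids or integer indices."""
        if len(which) and isinstance(which[0], str):
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = [lookup[s] for s in which]
        else:
            idx = list(which)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            depths=self.depths[:, idx],
            samples=[self.samples[i] for i in idx],
        )

    def copy(self) -> "VariantTable":
        return replace(
            self,
            genotypes=self.genotypes.copy(),
            depths=self.depths.copy(),
            alleles=list(self.alleles),
            samples=list(self.samples),
        )


@dataclass
class FilterConfig:
    """Site-level filter thresholds.

    ``max_site_missingness``: sites with a *greater* missing fraction are
    removed.  ``max_het_proportion``: sites where heterozygous calls make up
    at least this fraction of non-missing calls are removed (selfing species
    assumption: excess heterozygosity indicates mapping artefacts).
    ``min_depth``: default minimum per-genotype depth for masking.
    """

    max_site_missingness: float = 0.5
    max_het_proportion: float = 0.05
    min_depth: int = 3

    def __post_init__(self):
        if not (0.0 <= self.max_site_missingness <= 1.0):
            raise ValueError("max_site_missingness must be in [0,1]")
        if not (0.0 <= self.max_het_proportion <= 1.0):
            raise ValueError("max_het_proportion must be in [0,1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class FilterReport:
    n_input: int
    n_removed_missingness: int
    n_removed_het: int
    n_removed: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_sample_meta(path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample, status, region, country.

    A ``missingness`` column is accepted if present; otherwise attach one from
    a table with :func:`attach_missingness`.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "status", "region", "country"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata lacks columns: {sorted(missing_cols)}")
    if meta["sample"].duplicated().any():
        dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    bad = set(meta["status"]) - set(STATUSES)
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    if "missingness" in meta.columns:
        meta["missingness"] = meta["missingness"].astype(float)
        if ((meta["missingness"] < 0) | (meta["missingness"] > 1)).any():
            raise ValueError("missingness must be in [0,1]")
    return meta


def attach_missingness(meta: pd.DataFrame, table: VariantTable) -> pd.DataFrame:
    """Return meta with a ``missingness`` column computed from the table."""
    frac = table.sample_missingness()
    meta = meta.drop(columns=["missingness"], errors="ignore")
    return meta.merge(frac.rename("missingness"), left_on="sample",
                      right_index=True, how="left")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def read_vcf(path, meta: pd.DataFrame | None = None) -> VariantTable:
    """Decode a multi-sample VCF into a :class:`VariantTable`.

    GT is required; DP (FORMAT) is optional and becomes ``UNKNOWN_DEPTH``
    where absent.  ``./.`` and half-calls decode to MISSING.  Multiallelic
    records are preserved as multistate sites.  When ``meta`` is given, the
    VCF sample ids must match its ``sample`` column exactly (any order).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if meta is not None:
        meta_ids = set(meta["sample"])
        vcf_ids = set(samples)
        if meta_ids != vcf_ids:
            only_vcf = sorted(vcf_ids - meta_ids)
            only_meta = sorted(meta_ids - vcf_ids)
            raise SampleMismatchError(
                f"sample ids disagree; only in VCF: {only_vcf}; "
                f"only in metadata: {only_meta}")
    N = len(samples)

    chroms, positions, alleles, kinds = [], [], [], []
    gt_rows, dp_rows = [], []
    for i, var in enumerate(vcf):
        try:
            allele_row = (var.REF, *var.ALT)
            gts = np.array(var.genotypes, dtype=np.int16)[:, :2]
            # half-calls and ./. -> fully missing
            half = (gts == MISSING).any(axis=1)
            gts[half] = MISSING
            gts.sort(axis=1)
            dp = var.format("DP")
            if dp is None:
                dp_row = np.full(N, UNKNOWN_DEPTH, dtype=np.int32)
            else:
                dp_row = dp.reshape(-1).astype(np.int32)
                dp_row[dp_row < 0] = UNKNOWN_DEPTH
        except Exception as exc:  # noqa: BLE001 - surface record context
            raise VcfParseError(
                f"malformed VCF record #{i + 1} at "
                f"{var.CHROM}:{var.POS}: {exc}") from exc
        chroms.append(var.CHROM)
        positions.append(var.POS)
        alleles.append(allele_row)
        kinds.append(any(len(a) != len(allele_row[0]) for a in allele_row[1:]))
        gt_rows.append(gts)
        dp_rows.append(dp_row)

    S = len(positions)
    table = VariantTable(
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        alleles=alleles,
        genotypes=(np.stack(gt_rows) if S else
                   np.empty((0, N, 2), dtype=np.int16)),
        depths=(np.stack(dp_rows) if S else
                np.empty((0, N), dtype=np.int32)),
        samples=samples,
        site_kind=np.array(kinds, dtype=bool),
    )
    table = _sort_within_chromosomes(table)
    table.validate()
    return table


def _sort_within_chromosomes(table: VariantTable) -> VariantTable:
    """Stable-sort sites by position within each chromosome, keeping the
    chromosome order of first appearance (the VCF header / body order)."""
    order = {c: i for i, c in enumerate(pd.unique(table.chroms))}
    chrom_rank = np.array([order[c] for c in table.chroms])
    idx = np.lexsort((table.positions, chrom_rank))
    if (idx == np.arange(len(idx))).all():
        return table
    return replace(
        table,
        chroms=table.chroms[idx],
        positions=table.positions[idx],
        alleles=[table.alleles[i] for i in idx],
        genotypes=table.genotypes[idx],
        depths=table.depths[idx],
        site_kind=table.site_kind[idx],
    )


def write_vcf(table: VariantTable, path) -> None:
    """Write the table as a plain VCF 4.2 with GT:DP per genotype."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(table.chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for s in range(table.n_sites):
            ref = table.alleles[s][0]
            alt = ",".join(table.alleles[s][1:]) or "."
            fields = []
            for n in range(table.n_samples):
                a, b = table.genotypes[s, n]
                gt = "./." if a == MISSING else f"{a}/{b}"
                dp = table.depths[s, n]
                fields.append(gt if dp == UNKNOWN_DEPTH else f"{gt}:{dp}")
            fmt = "GT" if (table.depths[s] == UNKNOWN_DEPTH).all() else "GT:DP"
            fh.write(f"{table.chroms[s]}\t{table.positions[s]}\t.\t{ref}\t"
                     f"{alt}\t.\t.\t.\t{fmt}\t" + "\t".join(fields) + "\n")


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# masking and filtering
# ---------------------------------------------------------------------------


def mask_low_depth(table: VariantTable, min_depth: int,
                   strict_unknown: bool = False) -> VariantTable:
    """Set genotypes with depth below ``min_depth`` to MISSING.

    Depth ``UNKNOWN_DEPTH`` passes by default so that depth-less inputs are
    untouched; ``strict_unknown=True`` masks unknown depths as well.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    known = table.depths != UNKNOWN_DEPTH
    low = known & (table.depths < min_depth)
    if strict_unknown:
        low = low | ~known
    out = table.copy()
    out.genotypes[low] = MISSING
    return out


def filter_sites(table: VariantTable,
                 cfg: FilterConfig | None = None) -> tuple[VariantTable, FilterReport]:
    """Remove sites by missingness and heterozygosity rules.

    A site is removed iff its missing fraction exceeds
    ``max_site_missingness`` or heterozygous calls make up at least
    ``max_het_proportion`` of its non-missing calls.  Sites with zero
    non-missing calls fall under the missingness rule (no division occurs).
    """
    cfg = cfg or FilterConfig()
    if table.n_sites == 0:
        raise ValueError("empty variant table")
    missing = table.missing_mask()
    n_missing = missing.sum(axis=1)
    n_valid = table.n_samples - n_missing
    miss_frac = n_missing / table.n_samples
    fail_miss = (miss_frac > cfg.max_site_missingness) | (n_valid == 0)
    n_het = table.het_mask().sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        het_frac = np.where(n_valid > 0, n_het / np.maximum(n_valid, 1), 0.0)
    fail_het = (n_valid > 0) & (het_frac >= cfg.max_het_proportion)
    keep = ~(fail_miss | fail_het)
    report = FilterReport(
        n_input=table.n_sites,
        n_removed_missingness=int(fail_miss.sum()),
        n_removed_het=int(fail_het.sum()),
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return table.take_sites(keep), report
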