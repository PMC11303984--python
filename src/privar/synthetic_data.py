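"""Synthetic cohorts with the statistical structure of a selfing crop.

The generator emulates the features the analysis depends on, with known
truth: predominant homozygosity (selfing), higher wild than domesticated
diversity (a domestication bottleneck retains only part of the wild
polymorphism), group-private homozygous variants planted per sample, exact
duplicate accessions, one low-coverage high-missingness "ancient" sample
carrying eroded variants absent from the extant pool, near-fixed
domestication alleles rare in the wild (some in tight physical blocks), and
a chloroplast alignment with a star-like dominant haplogroup plus a deeply
diverged minor haplogroup.

It is a pool-and-subsample model, not a coalescent: every planted quantity
(private-variant counts, duplicate identity, diagnostic alleles, haplotype
assignments) is exact by construction, which is what makes pipeline
round-trip tests possible.  All outputs are bit-reproducible from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MISSING, VariantTable, write_sample_meta, write_vcf

ANCIENT_ID = "ANC001"

DEFAULT_REGIONS = {
    "Turkey+": 0.50,
    "S Europe": 0.75,
    "N Africa": 1.00,
    "S Asia": 1.25,
    "E Africa+": 1.50,
    "C Asia": 1.75,
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AncientSpec:
    missingness: float = 0.4
    depth_mean: float = 2.0
    n_eroded: int = 100   #: eroded variants, homozygous and unique to the
                          #: ancient sample — private doubletons by design


@dataclass
class ChloroplastSpec:
    """Star-like major haplogroup plus one deeply diverged minor group."""

    alignment_length: int = 2000
    major_center_n: int = 40        # samples on the central haplotype
    n_satellites: int = 6           # 1–2-substitution satellites
    satellite_n: int = 3            # samples per satellite
    minor_center_n: int = 6
    minor_satellites: int = 2
    inter_group_distance: int = 16  # substitutions between group centres
    n_partial: int = 1              # samples with masked positions
    partial_missing_fraction: float = 0.25


@dataclass
class SimConfig:
    seed: int = 0
    n_wild: int = 40
    n_landrace: int = 80
    n_cultivar: int = 30
    n_sites: int = 20_000
    n_chromosomes: int = 7
    chromosome_length: int = 500_000_000
    wild_polymorphism: float = 0.30      # background sites polymorphic in wild
    bottleneck_retention: float = 0.40   # fraction kept polymorphic after
                                         # domestication
    het_rate: float = 0.005              # residual heterozygosity (selfing)
    missing_rate: float = 0.02
    depth_mean: float = 20.0
    depth_dispersion: float | None = 5.0  # negative-binomial r; None = exact
    indel_fraction: float = 0.05
    multiallelic_fraction: float = 0.01
    n_diagnostic: int = 60               # near-fixed domestication alleles
    n_diagnostic_blocks: int = 3         # tight physical blocks among them
    diagnostic_block_size: int = 10
    wild_diagnostic_freq: float = 0.10   # wild frequency of the dom allele
    planted_pv: dict = field(default_factory=dict)   # sample id -> count
    ancient: AncientSpec | None = None
    duplicate_of: tuple = ()             # sample ids to copy exactly
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    region_site_base: int = 150          # region-specific polymorphic sites
                                         # per unit of diversity multiplier
    chloroplast: ChloroplastSpec = field(default_factory=ChloroplastSpec)

    def __post_init__(self):
        for name in ("wild_polymorphism", "bottleneck_retention", "het_rate",
                     "missing_rate", "indel_fraction",
                     "multiallelic_fraction", "wild_diagnostic_freq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class TruthTables:
    planted_pv: dict            # sample -> planted private-variant count
    duplicates: dict            # copy id -> source id
    diagnostic_sites: pd.DataFrame  # site, allele_index, block
    theta_by_region: dict       # realized per-site Watterson per region
    haplotypes: dict | None = None  # chloroplast sample -> haplotype label


# ---------------------------------------------------------------------------
# nuclear simulation
# ---------------------------------------------------------------------------


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def simulate_nuclear(cfg: SimConfig) -> tuple[VariantTable, pd.DataFrame, TruthTables]:
    """Simulate the nuclear genotype matrix, metadata and truth tables."""
    rng = np.random.default_rng(cfg.seed)

    # -- samples ------------------------------------------------------------
    wild = [f"W{i:03d}" for i in range(1, cfg.n_wild + 1)]
    landrace = [f"L{i:03d}" for i in range(1, cfg.n_landrace + 1)]
    cultivar = [f"C{i:03d}" for i in range(1, cfg.n_cultivar + 1)]
    samples = wild + landrace + cultivar
    statuses = (["wild"] * cfg.n_wild + ["landrace"] * cfg.n_landrace
                + ["cultivar"] * cfg.n_cultivar)
    region_names = list(cfg.regions) or ["all"]
    regions = []
    dom_counter = 0
    for st in statuses:
        if st == "wild":
            regions.append("wild range")
        else:
            regions.append(region_names[dom_counter % len(region_names)])
            dom_counter += 1
    if cfg.ancient is not None:
        samples.append(ANCIENT_ID)
        statuses.append("ancient")
        regions.append(region_names[0])
    N = len(samples)
    status_arr = np.array(statuses, dtype=object)
    is_wild = status_arr == "wild"
    is_dom = np.isin(status_arr, ("landrace", "cultivar"))
    is_ancient = status_arr == "ancient"
    region_arr = np.array(regions, dtype=object)

    # -- site bookkeeping ---------------------------------------------------
    S = cfg.n_sites
    planted_items = sorted(cfg.planted_pv.items())
    n_planted = sum(c for _, c in planted_items)
    n_eroded = cfg.ancient.n_eroded if cfg.ancient else 0
    n_region_sites = {r: int(round(cfg.region_site_base * m))
                      for r, m in cfg.regions.items()}
    n_special = (n_planted + n_eroded + cfg.n_diagnostic
                 + sum(n_region_sites.values()))
    if n_special > S:
        raise ValueError(f"config needs {n_special} special sites "
                         f"but only {S} sites requested")
    unknown = {s for s, _ in planted_items if s not in samples}
    if unknown:
        raise ValueError(f"planted_pv names unknown samples: {sorted(unknown)}")

    perm = rng.permutation(S)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = perm[cursor:cursor + k]
        cursor += k
        return out

    # diagnostic blocks are runs of consecutive site indices -> physically
    # tight once positions are laid down in index order
    block_sites = []
    n_block_total = cfg.n_diagnostic_blocks * cfg.diagnostic_block_size
    n_block_total = min(n_block_total, cfg.n_diagnostic)
    if cfg.n_diagnostic_blocks and cfg.diagnostic_block_size:
        starts = rng.choice(S - cfg.diagnostic_block_size,
                            size=cfg.n_diagnostic_blocks, replace=False)
        for st in sorted(starts):
            block_sites.extend(range(st, st + cfg.diagnostic_block_size))
        block_sites = list(dict.fromkeys(block_sites))[:n_block_total]
    block_set = set(block_sites)
    perm = perm[~np.isin(perm, block_sites)]
    diag_scatter = take(cfg.n_diagnostic - len(block_sites))
    diag_sites = np.array(sorted(block_set | set(diag_scatter.tolist())),
                          dtype=np.int64)
    planted_sites = {s: take(c) for s, c in planted_items}
    eroded_sites = take(n_eroded)
    region_sites = {r: take(k) for r, k in n_region_sites.items()}
    background = perm[cursor:]

    # -- per-site per-sample alternate-allele probabilities ------------------
    F = np.zeros((S, N), dtype=np.float32)

    bg_poly = background[rng.random(len(background)) < cfg.wild_polymorphism]
    q_wild = rng.uniform(0.1, 0.9, size=len(bg_poly)).astype(np.float32)
    F[bg_poly] = q_wild[:, None]
    retained = rng.random(len(bg_poly)) < cfg.bottleneck_retention
    q_dom = np.clip(q_wild + rng.normal(0, 0.1, len(bg_poly)).astype(np.float32),
                    0.02, 0.98)
    dom_cols = is_dom | is_ancient
    F[np.ix_(bg_poly[retained], dom_cols)] = q_dom[retained][:, None]
    F[np.ix_(bg_poly[~retained], dom_cols)] = 0.0

    for r, sites in region_sites.items():
        in_region = is_dom & (region_arr == r)
        q = rng.uniform(0.2, 0.8, size=len(sites)).astype(np.float32)
        F[np.ix_(sites, ~in_region)] = 0.0
        F[np.ix_(sites, in_region)] = q[:, None]

    F[np.ix_(diag_sites, dom_cols)] = 1.0
    if cfg.ancient is not None:
        F[diag_sites, samples.index(ANCIENT_ID)] = 0.95
    F[np.ix_(diag_sites, is_wild)] = cfg.wild_diagnostic_freq

    # -- draw homozygous genotypes ------------------------------------------
    alt = rng.random((S, N), dtype=np.float32) < F
    G = np.zeros((S, N, 2), dtype=np.int16)
    G[alt] = 1

    # planted and eroded variants: unique homozygous alternate alleles
    for s, sites in planted_sites.items():
        G[sites] = 0
        G[sites, samples.index(s)] = 1
    if cfg.ancient is not None and n_eroded:
        G[eroded_sites] = 0
        G[eroded_sites, samples.index(ANCIENT_ID)] = 1

    # residual heterozygosity on background sites only, so planted counts
    # stay exact
    if cfg.het_rate > 0:
        het = rng.random((S, N)) < cfg.het_rate
        special = np.zeros(S, dtype=bool)
        for sites in planted_sites.values():
            special[sites] = True
        if n_eroded:
            special[eroded_sites] = True
        het[special] = False
        G[het] = (0, 1)

    # -- alleles, site kinds, multiallelic decoration ------------------------
    alleles: list = [("A", "G")] * S
    kind = np.zeros(S, dtype=bool)
    protected = np.zeros(S, dtype=bool)
    for sites in planted_sites.values():
        protected[sites] = True
    if n_eroded:
        protected[eroded_sites] = True
    protected[diag_sites] = True
    free = np.flatnonzero(~protected)
    n_indel = int(round(cfg.indel_fraction * len(free)))
    indel_sites = rng.choice(free, size=n_indel, replace=False)
    kind[indel_sites] = True
    for s in indel_sites:
        alleles[s] = ("A", "AT")
    n_multi = int(round(cfg.multiallelic_fraction * len(free)))
    multi_sites = rng.choice(np.setdiff1d(free, indel_sites, assume_unique=False),
                             size=n_multi, replace=False)
    for s in multi_sites:
        alleles[s] = ("A", "G", "T")
        carriers = rng.choice(N, size=min(3, N), replace=False)
        G[s, carriers] = 2

    # -- depth and missingness ----------------------------------------------
    mean_dp = np.full(N, cfg.depth_mean)
    miss_rate = np.full(N, cfg.missing_rate)
    if cfg.ancient is not None:
        ai = samples.index(ANCIENT_ID)
        mean_dp[ai] = cfg.ancient.depth_mean
        miss_rate[ai] = cfg.ancient.missingness
    if cfg.depth_dispersion is None:
        depths = np.broadcast_to(
            np.round(mean_dp).astype(np.int32), (S, N)).copy()
    else:
        r = cfg.depth_dispersion
        p = r / (r + mean_dp)
        depths = rng.negative_binomial(r, p, size=(S, N)).astype(np.int32)
    missing = rng.random((S, N)) < miss_rate[None, :]
    G[missing] = MISSING

    # -- exact duplicates ----------------------------------------------------
    dup_map = {}
    for src in cfg.duplicate_of:
        if src not in samples:
            raise ValueError(f"duplicate source {src!r} not a sample")
        copy_id = f"{src}dup"
        j = samples.index(src)
        G = np.concatenate([G, G[:, j:j + 1]], axis=1)
        depths = np.concatenate([depths, depths[:, j:j + 1]], axis=1)
        samples = samples + [copy_id]
        statuses = statuses + [statuses[j]]
        regions = regions + [regions[j]]
        dup_map[copy_id] = src

    # -- positions ------------------------------------------------------------
    per_chrom = np.array_split(np.arange(S), cfg.n_chromosomes)
    chroms = np.empty(S, dtype=object)
    positions = np.empty(S, dtype=np.int64)
    for ci, sites in enumerate(per_chrom):
        chroms[sites] = f"chr{ci + 1}H"
        mean_gap = max(2, cfg.chromosome_length // max(len(sites), 1))
        gaps = rng.integers(1, 2 * mean_gap, size=len(sites))
        positions[sites] = np.cumsum(gaps)

    table = VariantTable(
        chroms=chroms, positions=positions, alleles=alleles,
        genotypes=G, depths=depths, samples=list(samples),
        site_kind=kind)
    table.validate()

    meta = pd.DataFrame({
        "sample": samples, "status": statuses, "region": regions,
        "country": ["synthetic"] * len(samples),
    })
    meta["missingness"] = table.sample_missingness().to_numpy()

    theta = _realized_regional_theta(table, meta)
    diag_frame = pd.DataFrame({
        "site": diag_sites,
        "allele_index": 1,
        "block": [s in block_set for s in diag_sites],
    })
    truth = TruthTables(
        planted_pv={s: len(v) for s, v in planted_sites.items()},
        duplicates=dup_map,
        diagnostic_sites=diag_frame,
        theta_by_region=theta,
    )
    return table, meta, truth


def _realized_regional_theta(table: VariantTable, meta: pd.DataFrame) -> dict:
    """Per-site Watterson's Theta over each domesticated region's samples."""
    from .diversity import watterson_theta_genotypes

    out = {}
    dom = meta[meta["status"].isin(("landrace", "cultivar"))]
    for region, block in dom.groupby("region"):
        if len(block) < 2:
            continue
        out[region] = watterson_theta_genotypes(table, list(block["sample"]))
    return out


# ---------------------------------------------------------------------------
# chloroplast simulation
# ---------------------------------------------------------------------------


def simulate_chloroplast(cfg: SimConfig) -> tuple[dict, pd.DataFrame]:
    """Simulate the chloroplast alignment and per-sample haplotype truth.

    Returns ({sample id: sequence}, truth frame with columns sample,
    haplotype, haplogroup).  Every substitution that defines a haplotype is
    carried by >= 2 samples so the corresponding column stays scorable.
    """
    cp = cfg.chloroplast
    rng = np.random.default_rng(cfg.seed + 10_007)
    L = cp.alignment_length
    n_subs_needed = (cp.inter_group_distance
                     + 2 * cp.n_satellites + 2 * cp.minor_satellites + 8)
    if n_subs_needed > L:
        raise ValueError("inter-group distance exceeds available columns")
    base = rng.choice(list("ACGT"), size=L)
    free_cols = list(rng.permutation(L))
    used_cols: list = []

    def mutate(seq, n_cols):
        cols = [free_cols.pop() for _ in range(n_cols)]
        used_cols.extend(cols)
        out = seq.copy()
        for c in cols:
            choices = [b for b in "ACGT" if b != out[c]]
            out[c] = choices[rng.integers(0, 3)]
        return out, cols

    haplos = {"A1": base}
    group_of = {"A1": "A"}
    for i in range(cp.n_satellites):
        haplos[f"A{i + 2}"], _ = mutate(base, int(rng.integers(1, 3)))
        group_of[f"A{i + 2}"] = "A"
    minor_center, inter_cols = mutate(base, cp.inter_group_distance)
    haplos["B1"] = minor_center
    group_of["B1"] = "B"
    for i in range(cp.minor_satellites):
        haplos[f"B{i + 2}"], _ = mutate(minor_center, 1)
        group_of[f"B{i + 2}"] = "B"

    counts = {"A1": cp.major_center_n, "B1": cp.minor_center_n}
    for i in range(cp.n_satellites):
        counts[f"A{i + 2}"] = cp.satellite_n
    for i in range(cp.minor_satellites):
        counts[f"B{i + 2}"] = max(2, cp.satellite_n - 1)

    seqs, rows = {}, []
    si = 0
    for label, n in counts.items():
        for _ in range(n):
            si += 1
            sid = f"cp{si:03d}"
            seqs[sid] = "".join(haplos[label])
            rows.append({"sample": sid, "haplotype": label,
                         "haplogroup": group_of[label]})
    # partial assemblies: ambiguity-masked copies of the major centre.
    # Masked columns are monomorphic columns plus a minority of the
    # inter-group columns, so the vector stays compatible with exactly one
    # haplotype (its own) over the scored positions.
    n_mask = int(cp.partial_missing_fraction * L)
    maskable_mono = [c for c in range(L) if c not in set(used_cols)]
    mask_cols = (list(inter_cols[: max(1, len(inter_cols) // 3)])
                 + maskable_mono)[:n_mask]
    for i in range(cp.n_partial):
        si += 1
        sid = f"cp{si:03d}partial"
        chars = list("".join(haplos["A1"]))
        for c in mask_cols:
            chars[c] = "N"
        seqs[sid] = "".join(chars)
        rows.append({"sample": sid, "haplotype": "A1", "haplogroup": "A"})
    return seqs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# preset scenario
# ---------------------------------------------------------------------------


@dataclass
class ScenarioBundle:
    config: SimConfig
    table: VariantTable
    meta: pd.DataFrame
    truth: TruthTables
    chloroplast: dict
    chloroplast_truth: pd.DataFrame


def erosion_config(seed: int = 0) -> SimConfig:
    """The standard genetic-erosion study configuration.

    40 wild, 80 landraces, 30 cultivars and one ancient sample over 20,000
    sites; the ancient sample has 40% missingness, mean depth 2 and 0.5%
    eroded private variants; two landraces are duplicated exactly; six
    regions span a diversity gradient, with per-sample private-variant
    planting proportional to each region's diversity multiplier.  Wild
    samples receive heavier planting (mean 0.6% of sites) than any
    domesticated sample, reproducing the wild > ancient > extant
    domesticated ordering of per-sample uniqueness.
    """
    cfg = SimConfig(seed=seed, ancient=AncientSpec(n_eroded=100),
                    duplicate_of=("L001", "L002"))
    rng = np.random.default_rng(seed + 20_011)
    region_names = list(cfg.regions)
    planted = {}
    for i in range(1, cfg.n_wild + 1):
        planted[f"W{i:03d}"] = int(rng.poisson(120.0))
    dom_counter = 0
    # mirror the round-robin region assignment used by simulate_nuclear
    sample_regions = []
    for i in range(1, cfg.n_landrace + 1):
        sample_regions.append((f"L{i:03d}",
                               region_names[dom_counter % len(region_names)]))
        dom_counter += 1
    for i in range(1, cfg.n_cultivar + 1):
        sample_regions.append((f"C{i:03d}",
                               region_names[dom_counter % len(region_names)]))
        dom_counter += 1
    for sid, region in sample_regions:
        lam = 15.0 * cfg.regions[region]
        planted[sid] = int(rng.poisson(lam))
    cfg.planted_pv = planted
    return cfg


def scenario_erosion(seed: int = 0, outdir=None) -> ScenarioBundle:
    """Generate the full erosion-scenario fixture bundle.

    With ``outdir`` the bundle is also written to disk: VCF, metadata TSV,
    chloroplast FASTA, truth TSVs and a JSON config echo.
    """
    cfg = erosion_config(seed)
    table, meta, truth = simulate_nuclear(cfg)
    cp_seqs, cp_truth = simulate_chloroplast(cfg)
    truth.haplotypes = dict(zip(cp_truth["sample"], cp_truth["haplotype"]))
    bundle = ScenarioBundle(cfg, table, meta, truth, cp_seqs, cp_truth)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: ScenarioBundle, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(bundle.table, out / "nuclear.vcf")
    write_sample_meta(bundle.meta, out / "samples.tsv")
    with open(out / "chloroplast.fasta", "w") as fh:
        for sid, seq in bundle.chloroplast.items():
            fh.write(f">{sid}\n{seq}\n")
    bundle.chloroplast_truth.to_csv(out / "truth_haplotypes.tsv", sep="\t",
                                    index=False)
    pd.Series(bundle.truth.planted_pv, name="planted_pv").rename_axis(
        "sample").to_csv(out / "truth_planted_pv.tsv", sep="\t")
    bundle.truth.diagnostic_sites.to_csv(out / "truth_diagnostic_sites.tsv",
                                         sep="\t", index=False)
    pd.Series(bundle.truth.theta_by_region, name="theta").rename_axis(
        "region").to_csv(out / "truth_theta.tsv", sep="\t")
    pd.Series(bundle.truth.duplicates, name="source").rename_axis(
        "copy").to_csv(out / "truth_duplicates.tsv", sep="\t")
    with open(out / "config.json", "w") as fh:
        fh.write(bundle.config.to_json())
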