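# privar

Per-sample **private-variant (PV) statistics**, **chloroplast haplotype
networks** and **diversity estimators** for detecting genetic erosion in
predominantly self-pollinating crops such as barley.

When an ancient specimen carries many alleles that no extant accession
carries, diversity has been lost from the gene pool since that specimen
grew.  `privar` implements the analytical machinery needed to make that
argument quantitative on modern variant-call data:

* **Private variants.**  For each sample, count alleles confined to that
  sample in homozygous state — *private doubleton* SNPs (both copies of an
  allele in one homozygous carrier) and private homozygous indels.
  Heterozygous *singletons* are excluded: in a selfing species they mostly
  reflect somatic mutations or mapping error.  The per-sample statistic is

  ```
  PV% = 100 × (private doubletons + private homozygous indels)
             / (non-missing genotype calls of the sample)
  ```

  computed at several minimum-depth genotype thresholds (minDP 2–5) and
  averaged, making it usable for low-coverage ancient DNA with moderate
  (<50%) missingness.  Outliers are screened with the modified Thompson
  Tau test and group z-scores; regional mean PV% is correlated with
  regional Watterson's θ.

* **Duplicate pruning.**  Flat-weighted identity-by-state (IBS) similarity
  over mutually non-missing sites; connected components above a threshold
  (default 0.985) are duplicate groups, keeping the member with the least
  missing data.  Duplicates must go first — an exact copy zeroes its
  twin's private variants.

* **Chloroplast phylogeography.**  Alignment columns with a minor state in
  ≥ 2 samples are scored; complete state vectors define haplotypes
  (partial, ancient assemblies are assigned when compatible with exactly
  one haplotype); a median-joining network (minimum-spanning connections
  plus inferred median vectors that shorten the network) relates them;
  haplogroups are labelled from seed haplotypes; `T = (d/L) / 2μ` converts
  substitution counts to divergence times.

* **Diversity.**  Pairwise-deletion nucleotide diversity π, Watterson's
  θ = S/(a·L), haplotype diversity H = N/(N−1)(1 − Σxᵢ²), and rarefied
  allelic richness A(g).

* **Group-level structure.**  Variable-position partition among cultivars
  / landraces / wild (how much wild diversity survived domestication), a
  permutation test for physical clustering of group-specific SNPs,
  near-fixed domestication alleles (domesticated frequency > 0.95, wild
  < 0.25) with per-sample domestication scores, and genotype PCA with
  Patterson normalisation.

* **Synthetic cohorts.**  A seeded generator emulates the statistical
  structure of such datasets — selfing homozygosity, a domestication
  bottleneck, planted private variants, exact duplicates, one
  low-coverage ancient sample with eroded variants, and a star-like
  chloroplast haplogroup with a deeply diverged minor group — with exact
  truth tables, so the whole pipeline is testable without any download.

## Worked example

```python
import privar

bundle = privar.scenario_erosion(seed=1)           # synthetic cohort
res = privar.run_pv_pipeline(bundle.table, bundle.meta,
                             privar.RunConfig(seed=1))
anc = res["summary"].loc["ANC001"]
print(res["dropped"], anc["pv_percent_mean"], anc["z_vs_domesticated"],
      res["regional_r"])
```

prints (formatted):

```
duplicates dropped : ['L001dup', 'L002dup']
ancient PV%        : 0.515 +/- 0.070
z vs domesticated  : 12.05
z vs wild          : -1.73
Tau outlier        : True
regional r, p      : 0.971, 1.27e-03
```

Both planted duplicate pairs are caught by the IBS screen.  The ancient
sample carries private variants in 0.515% of its valid calls — twelve
standard deviations above the extant domesticated barley and flagged as a
Thompson Tau outlier, yet slightly *below* the wild mean: the signature of
an eroded domesticated gene pool.  The PV proportion is stable across
minDP 2–5 (±0.07) despite the sample's 40% missingness, and regional mean
PV% tracks regional diversity (r = 0.97 over six regions).

The same analyses are available from the shell:

```bash
privar --seed 1 simulate --out bundle/
privar pv bundle/nuclear.vcf bundle/samples.tsv --out reports/
privar cpnet bundle/chloroplast.fasta --out reports/cp/
```

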