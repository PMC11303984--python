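# Methods

This note documents the statistical model behind `privar`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Private-variant statistics

A *private variant* (PV) is an allele observed in exactly one individual
of a sample set, in homozygous state.  Two classes are counted: private
doubleton SNPs (allele count 2, both copies in one homozygous carrier)
and private homozygous indels (the same single-carrier homozygous pattern
at a site where some allele's length differs from the reference's).
Heterozygous singletons (allele count 1) are excluded: in a predominantly
self-pollinating species, residual heterozygous calls overwhelmingly
reflect somatic mutation, assembly or mapping error rather than standing
variation, and singleton counts correlate poorly with the homozygous
classes.

The per-sample statistic is `PV% = 100 × PV count / non-missing calls of
that sample`.  Normalising by the sample's own valid calls (rather than
the cohort total) makes modern and high-missingness ancient samples
comparable.  The statistic is recomputed at each minimum-depth threshold
minDP ∈ {2,3,4,5}: masking to a new depth floor defines a new
genotype-calling regime, so singleton/doubleton status is re-derived from
scratch each time, and the denominator is the per-sample non-missing call
count over *all* retained sites at that masking, not only
polymorphic-after-masking sites.  The mean and standard deviation across
settings quantify robustness.  Genotypes with *unknown* depth (records
carrying no DP) pass the mask by default, so depth-less inputs are left
intact; a strict flag masks them instead.

Why this is robust for moderately missing samples: both the PV count and
the valid-call denominator shrink roughly proportionally as the depth
floor rises, so their ratio is approximately invariant until missingness
becomes extreme, at which point the standard deviation across minDP
settings exposes the instability.

Inference helpers: group z-scores use the sample standard deviation
(n−1); the reference group excludes the scored sample itself, and
hybrid/feral accessions belong to neither the wild nor the domesticated
reference.  The modified Thompson Tau screen iterates: with n remaining
points, τ = t₍α/2,n−2₎(n−1)/(√n·√(n−2+t²)); the largest absolute
deviation from the mean is an outlier iff it exceeds τ·s; the point is
removed and the test repeats until nothing is flagged (α = 0.05 default,
configurable — the exact iteration scheme of the original procedure
varies between descriptions, so it is pinned here).  Pearson correlations
report the two-sided p from the exact t transform with n−2 degrees of
freedom.

## Site filters and duplicate pruning

Sites are removed when the missing fraction exceeds 0.5 (strictly) or
heterozygous calls reach 5% of non-missing calls (inclusive, per the
selfing argument above).  A site with zero non-missing calls is removed
under the missingness rule without any division.  Filtering is
idempotent.

IBS similarity between two samples is the mean, over mutually non-missing
sites, of the per-site share ∈ {0, ½, 1} of allele slots identical by
state under the best order-free pairing; every comparable site weighs 1
("flat" weighting — no allele-frequency weighting, so the matrix is
reproducible without frequency estimates).  Duplicate groups are
*connected components* of the IBS > 0.985 graph, not cliques: near-copies
of a common source should be grouped even when their mutual similarity
dips below the threshold.  Within a group the sample with the lowest
missingness is retained, ties breaking to the lexicographically smallest
id so reruns are deterministic.  The 0.985 default is a calibration
against known duplicate pairs in real exome datasets; it is exposed as a
parameter because the right value depends on marker density and error
rate.

## Diversity estimators

All sequence estimators use pairwise deletion: a column is included when
at least two sequences carry an unambiguous A/C/G/T there (gaps and IUPAC
codes are missing).  π sums, over included columns, the mean pairwise
difference among the valid sequences at that column, divided by the
number of included columns.  Watterson's θ = S/(a·L) counts included
segregating columns, with n taken as the number of sequences in the group
rather than per-column valid counts — at the missingness levels these
data show, the deviation is negligible, and the group-level n keeps the
estimator comparable across groups (flagged configurable in the code).
Haplotype diversity uses the unbiased H = N/(N−1)(1 − Σxᵢ²).  Allelic
richness uses the rarefaction form A(g) = Σₐ[1 − C(N−Nₐ,g)/C(N,g)]
(expected distinct alleles in a size-g subsample without replacement),
each haplotype counting as one allele; g defaults to the smallest
compared group's N, because correcting for unequal group sizes is the
point of the statistic.  For genotype matrices, a θ variant counts a site
as segregating when ≥ 2 distinct alleles occur among the subset's
non-missing calls, with n = 2 × samples allele copies.

## Chloroplast haplotypes and the median-joining network

Scored positions are alignment columns where, among non-missing states,
at least two states occur and the minor state is carried by ≥ 2
sequences — singleton states at the chloroplast are more likely assembly
artefacts than real variation.  An optional BED exclusion mask (0-based
half-open, converted internally to the 1-based closed convention used
throughout) removes regions such as the chloroplast segment with a
diverged mitochondrial paralog whose reads contaminate assemblies.

Complete state vectors define haplotypes.  A partial vector is assigned
to an existing haplotype iff it is compatible (equal at every non-missing
position) with exactly one of them; ambiguity or a missing fraction above
`max_missing` (default 0.5) leaves it unassigned.  This is what lets a
low-coverage ancient assembly with dozens of ambiguous positions still be
typed when only one haplotype matches.

The median-joining network alternates: build the ε-relaxed minimum
spanning network over the current node set (ε = 0 default — the
parsimonious union of all minimum spanning trees; an edge at distance w
joins nodes not already connected by pairs at distance ≤ w − ε − 1);
propose per-position-majority median vectors for every triplet sharing a
node in that network (a position where all three states differ expands
all tied states, capped at 1000 candidates per iteration to guarantee
termination); greedily add the median that most shortens the
spanning-tree length; repeat until no median helps, then prune medians
whose removal leaves the spanning-tree length unchanged.  Observed
haplotypes are never pruned and the result is connected.

The network's `length` is defined as the spanning-tree weight over the
final node set — the quantity the algorithm minimises and the one
comparable to an exact Steiner-tree optimum (the test suite checks
equality against a Dreyfus–Wagner oracle on small binary cases).  Where
exact ties produce alternative connections, the edge set retains the
reticulations, so the *summed* edge weight can exceed `length`; the node
set and `length` are tie-invariant.

Haplogroup labels propagate from user-supplied seed haplotypes by
shortest weighted path in the network, ties resolving to UNRESOLVED;
seeding is explicit because haplogroup designations are a curation
decision, not an inference.  Divergence dating uses T = (d/L)/(2μ) with a
user-supplied substitution rate; both the rate and the compared fragment
length are inputs, not package constants.

## Group-level analyses

"Variable in a group" means ≥ 2 distinct alleles among the group's
non-missing calls (a heterozygote carries both) — the minimal reading of
a variable position.  The clustering test statistic is the mean
per-chromosome nearest-neighbour base-pair distance among the specific
sites (mean adjacent gap is available behind a flag); the null re-draws
equal-sized uniform subsets of all variable sites, and the empirical
p-value is (1 + #{null ≤ observed})/(n_draws + 1), which is valid (never
zero) and uniform under the null.  Diagnostic domestication sites require
a domesticated allele frequency strictly > 0.95 and wild strictly < 0.25
over non-missing calls, either allele of a site qualifying — so both
derived sweeps and reference-allele sweeps count; hybrid/feral and
ancient samples belong to neither frequency group.  A sample's
domestication score is the fraction of its non-missing diagnostic sites
carrying ≥ 1 copy of the domesticated allele (a homozygous-only flag
exists because it is not knowable whether heterozygous carriers should
count; ≥ 1 copy is the default).  PCA encodes 0/1/2 dosages of the most
frequent non-reference allele, mean-imputes missing entries, and applies
Patterson's √(p(1−p)) scaling by default.

## The synthetic-data generator

The generator is a pool-and-subsample model, deliberately not a
coalescent: the tests need controlled truth values — exact planted PV
counts, exact duplicates, known diagnostic alleles, known haplotype
assignments — rather than realistic genealogies.  A coalescent backend
could be slotted in later without touching the analysis surface.

Defaults of the erosion scenario: 40 wild, 80 landrace and 30 cultivar
samples over 20,000 sites on 7 chromosomes; 30% of background sites
polymorphic in the wild pool, of which 40% stay polymorphic after the
domestication bottleneck; residual heterozygosity 0.005 and missingness
0.02 (selfing, modern exome data); negative-binomial depths with mean 20
(dispersion r = 5; a degenerate constant-depth mode supports exactness
tests); one ancient sample with 40% missingness, mean depth 2 and 100
eroded variants — alleles present only in that sample, homozygous, hence
private doubletons by construction (0.5% of sites, a magnitude chosen to
sit clearly above extant planting but below wild levels); two exact
duplicate pairs; six regions with diversity multipliers 0.5–1.75, each
contributing region-specific polymorphic sites and per-sample PV planting
with Poisson mean 15 × multiplier; wild samples are planted at Poisson
mean 120, reproducing the wild > ancient > extant-domesticated ordering
of uniqueness; 60 domestication-diagnostic sites (domesticated frequency
1.0, wild 0.10, the ancient sample carrying the domesticated allele with
probability 0.95), thirty of them in three tight 10-site physical blocks
to exercise the clustering test.  The chloroplast alignment has a
40-sample central haplotype with six 1–2-substitution satellites and a
minor haplogroup 16 substitutions away, every defining substitution
carried by ≥ 2 samples so its column stays scorable; one
ambiguity-masked partial copy of the central haplotype exercises partial
assignment.

What the generator does **not** emulate: linkage disequilibrium beyond
the planted blocks, realistic site-frequency spectra, sequencing-error
and reference-bias structure, aDNA damage patterns, or population
admixture.  Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery on data with the assumed
structure, not the field performance of the thresholds on any particular
real dataset.  Emergent behaviour is allowed for: e.g. bottleneck-lost
sites where the wild pool is nearly fixed for the alternate allele
legitimately qualify as reference-allele diagnostic sites, on top of the
planted ones.

## Numerical and determinism choices

All randomness flows through `numpy.random.default_rng(seed)`; equal
seeds give byte-identical VCF/FASTA/TSV outputs.  Genotype pairs are
stored sorted so unordered equality is positional.  Reports are plain TSV
and JSON with sorted keys and fixed float formatting, making pipeline
determinism testable at the byte level.  Problem sizes used by the test
suite (20,000 sites × ~150 samples for scenario runs, 100 scenario seeds
for the power checks, 200 replicates for calibration) were chosen so the
planted effects are comfortably detectable while a full run stays cheap
on a single CPU.

## Known limitations

The greedy median-joining implementation matches the exact Steiner
optimum on the small cases the suite checks but is a heuristic in
general, as is every median-joining construction.  Watterson's θ with a
group-level n is slightly biased when missingness varies strongly across
columns.  The Thompson Tau screen assumes approximate normality of the
reference distribution; with heavy planting gradients the flagged set can
extend beyond the planted outlier (the tests therefore assert membership,
not uniqueness).  IBS-based duplicate detection cannot distinguish true
duplicates from identical twins of descent; passport reconciliation is
out of scope.
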