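# Methods

`riverpop` re-implements, as a tested library, the post-variant-calling
population-genomics workflow used for multi-species river-salmon
resequencing cohorts: QC and filtering of a multi-sample VCF, admixture-based
population structure with ancestry-threshold group assignment, diversity and
relatedness statistics, runs of homozygosity, group-private alleles,
cross-assembly variant mapping, and extended-haplotype selection scans. The
pipeline starts at a called VCF; read alignment, variant calling and score
recalibration are out of scope, as are phasing (haplotype input must be
pre-phased) and demographic inference itself (only the mutation-rate scaling
arithmetic feeding it is included).

## Synthetic cohort generator

Real multi-terabyte resequencing cohorts are impractical as test fixtures, so
every stage is exercised against a generator with complete ground truth.

**Divergence model.** Population allele frequencies follow the
Balding–Nichols model: for ancestral frequency `p` and divergence parameter
`F`, population frequency is `Beta(p(1-F)/F, (1-p)(1-F)/F)`, so `F` directly
sets the expected Fst against the ancestral pool. This was chosen over
coalescent simulation because the downstream statistics need controllable
allele-frequency divergence and local haplotype structure, not full
genealogies, and it runs at desk scale. Ancestral frequencies are drawn from
`Beta(0.8, 0.8)` truncated to `[0.02, 0.98]` to avoid a glut of unusable
rare variants.

**Haplotypes and LD.** Haplotypes come from a first-order copying process:
adjacent sites share a latent uniform quantile with probability
`exp(-distance / ld_decay)` (default decay 25 kb), which leaves marginal
frequencies untouched while making haplotype homozygosity decay with
physical distance — enough structure for EHH-family statistics to behave
realistically. This is not a recombination-graph model: long-range LD
patterns, recombination hotspots and gene conversion are absent, so passing
tests demonstrate correct statistics, not realism of fine-scale haplotype
structure.

**Injections.** On top of the neutral background the generator can plant
(i) group-private alleles with an exact carrier count (one heterozygous copy
per carrier), (ii) autozygous segments (the second haplotype copied from
the first across an interval, guaranteeing zero true heterozygotes), and
(iii) a selective sweep: a core haplotype copied onto a chosen fraction of
a population's haplotypes across a span, with the focal SNP tagging core
membership. All injection coordinates are recorded in the truth bundle.

**Observation model.** Per-cell depth is `Poisson(sample mean)` (default
16×, the cohort-wide average of the motivating study). A true heterozygote
whose `d` reads all sample one allele is called homozygous — probability
`2·0.5^d` — which reproduces the depth-dependent heterozygote dropout that
motivates the 15× depth threshold for diversity analyses; cells below the
calling depth (default 3 reads) are missing, and an independent error
(default 0.002) corrupts calls. Site QUAL is simulated as monotone in depth
with Gaussian noise; it is only consumed by window QC. Mapping artifacts,
paralog collapse and reference bias are not modeled.

## QC and filtering

Defaults follow the source pipeline: biallelic SNPs only; per-site
missingness ≤ 10%; mean site depth within [8, 100]× (inclusive bounds);
MAF ≥ 0.01; samples removed below 8× mean depth (15× for depth-sensitive
analyses). Percent-heterozygous keeps missing genotypes in the denominator
so values are standardized against the full variant set. The MAF filter's
default denominator is total alleles (2n), the convention under which the
published carrier bounds (8 het / 4 hom at n=360; 6 / 3 at n=277) hold
exactly; an observed-allele denominator is available. LD pruning is greedy
in position order with trailing 20 kb windows, dropping a site whose
genotype-dosage r² against a retained window-mate exceeds 0.4 or when two
sites are already retained in the window; missing cells are pairwise
excluded from r², and ties keep the earliest positions. This is
deterministic and order-stable but not guaranteed byte-identical to
`bcftools +prune` internals.

## Population structure

The admixture model is the standard binomial mixture: genotype `g_ij ~
Binomial(2, p_ij)`, `p_ij = Σ_k Q_ik F_kj`. It is fit by EM with
multiplicative updates (collapsed E/M steps as four matrix products per
iteration), clamping `F` to `[1e-6, 1-1e-6]`; the log-likelihood is monotone
and checked every iteration. Defaults: tolerance ΔL < 1e-4, max 2000
iterations, 3 random restarts keeping the best likelihood. K = 1 uses the
closed form. This is simpler than the quasi-Newton acceleration of the
ADMIXTURE program; cluster solutions agree in separable regimes but exact
numerical replication is a non-goal.

K is selected by held-out genotype cells: 5 folds each masking a disjoint
10% of non-missing cells, error = mean `(g/2 − p̂)²` on masked cells, best K
= argmin of the mean CV error. Squared error on dosage replaces binomial
deviance for simplicity; in the separable regimes tested the argmin agrees.
CV fits use a looser tolerance (1e-3, ≤ 500 iterations, 1 restart) since
ranking, not the final likelihood, is what matters.

Genotype PCA mean-imputes missing dosages and standardizes columns by
`sqrt(2p(1−p))` before eigendecomposition; component signs are fixed by
making each component's largest-magnitude loading positive. Environmental
PCA is prcomp-style column-standardized PCA of per-location variables.
Group assignment: a sample joins its maximum-ancestry cluster iff that
ancestry ≥ 0.7, else it is unassigned (and excluded from private-allele
analysis); at location level the mean ancestry decides, with below-threshold
locations flagged and their runner-up group recorded.

## Diversity, relatedness, ROH

**Ritland relatedness** uses the 1996 allele-frequency-weighted estimator;
for a biallelic locus the locus estimate is
`2(Sx_p·Sy_p/p + Sx_q·Sy_q/q − 1)` with equal locus weights (the `n−1`
weight is 1 for two alleles). Frequencies default to the full retained
sample set, so groups rich in private alleles look more related — the same
inflation the source analysis observed. Values below 0 and above 1 are
expected. Deduplication greedily drops the sample in the most pairs ≥ 0.15
(ties: later id) until no such pair remains.

**Nucleotide diversity** per site with `m` observed alleles and frequency
`p` is `(m/(m−1))·2p(1−p)`; the per-location value averages over the
dataset-wide retained SNP set (sites monomorphic within a location
contribute 0). This variant-sites-only convention matters: π here is per
retained SNP, not per genome base pair. Polymorphic-locus counts are sites
segregating within the location. Only samples at ≥ 15× mean depth are used
by default, because of the heterozygote-dropout bias below that depth.

**Fst** is Weir & Cockerham (1984): per-site variance components a
(among populations), b (among individuals) and c (within individuals) from
group sizes, allele frequencies and heterozygote frequencies, combined as
`Σa / Σ(a+b+c)`. Sites monomorphic overall or with fewer than two called
genotypes in any group are skipped and counted.

**ROH** follows PLINK 1.9 semantics: 50-SNP sliding windows are
"homozygous" with ≤ 1 heterozygote and ≤ 5 missing calls; a SNP is in ROH
when ≥ 5% of windows containing it are homozygous; maximal runs become
segments when ≥ 25 SNPs and ≥ 1000 kb, with density ≤ 50 kb/SNP and splits
at gaps > 1000 kb. The three length parameters are PLINK defaults because
the source lists those flags without values; all are configurable.
Chromosomes with fewer SNPs than one window yield no calls. The scanner is
verified identical to an independent brute-force window enumerator on
random instances.

**Mutation-rate scaling** multiplies a base rate by a cross-species
SNP-count ratio and rounds to 2 significant figures (e.g. 8.0e-9 × 1.73 →
1.4e-8; × 0.80 → 6.4e-9).

## Private alleles

An allele (REF or ALT) is private to a group when all its observed
carriers (≥ 1 copy; heterozygotes count) lie in that group and number at
least 3. Missing genotypes are never carriers — a variant observed only as
missing outside the focal group therefore cannot block privacy, a
documented limitation of strict observed-carrier semantics. Discovery runs
on the post-filter SNP set. Per-individual counts report how many of the
own group's private alleles each member carries.

## Cross-assembly mapping

Chaining is greedy per (query, subject, strand): sort by query start,
extend while both axes stay monotone (subject descending on the minus
strand) and the inter-member gap is ≤ 100 kb on both axes; chains under
10 kb of query span are dropped, as are exact self-hits. Greedy rather than
optimal DP chaining: it matches simple-script semantics and is
deterministic.

Lift-over extracts a 301 bp window (flank 150) around each variant and
searches both strands of every target sequence by edit distance (edlib,
up to 10% of window length). A placement wins when its score
(window length − distance) is ≥ 1.1× the runner-up's — duplicated targets
therefore yield `unmapped:ambiguous` — and the target base at the window
centre matches REF (identity), ALT (recorded ref/alt swap, genotypes
flipped accordingly), or their complements on the minus strand. Remaining
failures are `no_hit`, `allele_mismatch` or `edge` (variant within a flank
of the contig end). Flank size and margin are tuned for desk-scale
fixtures and configurable. The original pipeline's uniqueness and
allele-reconciliation rules are unpublished; these rules are explicit
replacements.

## Selection scan

EHH for a focal allele is the probability that two distinct carrier
haplotypes are identical over every site from the focal SNP to a point,
computed by prefix grouping and verified against exhaustive pair
enumeration; the walk stops below 0.05 (the first below-threshold point is
excluded) with no interpolation. iHH is the trapezoid integral of the curve
over physical distance, both sides. iHS is unpolarized: alleles are
labelled major/minor per site (no ancestral assumption), the raw score is
`ln(iHH_major / iHH_minor)`, standardized to mean 0 / sd 1 within
minor-allele-frequency bins of width 0.025 (sites in bins with < 2 scores
are flagged unstandardized); sites under MAF 0.05 are skipped. Rsb
integrates site-EHHS (homozygosity of all haplotypes, normalized to 1 at
the focal site) per group and standardizes `ln(iES_a/iES_b)` by median and
standard deviation. Two-sided p-values come from the standard normal on
the standardized scores, with no genomic-control correction.

Candidate regions tile each chromosome in 10 kb windows; a window is a
candidate when ≥ 8 markers reach −log10 p ≥ 10, and adjacent candidates
merge. The threshold applies to −log10 p, consistent with comparing it to
a Bonferroni threshold (−log10(α/n), ≈ 8.8–9.1 at tens of millions of
tests). Cross-species overlap scores each shared 10 kb window by the
minimum across species of the species' maximum −log10 p, so only windows
extreme in every species rank highly.

## Pipeline, determinism, problem sizes

`run_pipeline` validates the whole configuration up front (all problems
reported at once), executes stages in dependency order, and writes a JSON
manifest of per-stage row counts. One global seed is fanned out per stage
as `seed·1000003 + crc32(stage_name) mod 2^31`, so stages are decoupled and
every run is byte-reproducible.

Test and acceptance workloads use desk-scale cohorts chosen to keep each
property measurable: 3 populations × 20 diploids with 5000 LD-pruned SNPs
for K selection; 2 × 30 diploids × 20 000 sites for realized-Fst
calibration; 2 × 25 diploids, 6000 SNPs over 30 Mb with a 150 kb sweep for
the scan (the sweep must occupy well under 1% of markers, since
extended-haplotype signals are regional and the focal SNP is only expected
in the extreme tail when the swept region itself is a small fraction of
the scan); 500-SNP instances for ROH oracle equivalence. The K-selection
quantity is reported as the majority over 5 generator seeds because CV on
a 60-sample cohort is stochastic.

## Known limitations

- The copying-process LD model has no recombination map; iHS/Rsb behavior
  on real data with hotspots is untested here.
- The EM admixture fit and squared-error CV are stand-ins for ADMIXTURE's
  accelerated optimizer and binomial-deviance CV; agreement is expected in
  well-separated regimes only.
- LD pruning and ROH calling follow the documented parameter semantics but
  are not bug-for-bug replicas of bcftools/PLINK internals.
- Private-allele discovery cannot distinguish "absent" from "unobserved"
  outside the focal group.
- Lift-over assumes SNVs only and unique best placements; segmental
  duplications are reported unmapped rather than multi-mapped.
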