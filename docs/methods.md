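# Methods

## The generative model behind the synthetic panel

The package ships a generator whose output has the same statistical shape
as a nation-wide inbred rice germplasm panel, with the generating
parameters retained so downstream stages can be tested by parameter
recovery.

**Ancestral allele frequencies** follow the Balding–Nichols model: a base
frequency p_j ~ Uniform(0.1, 0.9) per locus, and for ancestor k a draw
f_kj ~ Beta(p_j(1−c_k)/c_k, (1−p_j)(1−c_k)/c_k), where c_k ∈ (0, 1) plays
the role of that ancestor's differentiation from the common base. For two
ancestors with parameter c, the ratio-of-averages Hudson F_ST between
their frequency rows has expectation c (numerator 2c·p(1−p), denominator
2p(1−p) per locus); a Monte-Carlo check at L = 10,000 over 10 seeds
reproduces c to ±0.005. c = 0 is rejected (the Beta parameters diverge).

**Ancestry ratios.** Pure subpopulations get near-degenerate rows: the
dominant ancestor's weight is 1 − Uniform(0, 0.03) (configurable floor at
0.95), the remainder spread over the other ancestors. An admixed
subpopulation draws its two parent weights from Dirichlet(8, 8). The
concentration 8 keeps every admixed accession's parent weights well inside
(0.05, 0.95) while giving the group visible spread — concentrated enough
that the admixed group forms its own recoverable cluster, which is the
regime the default fixture is designed to exercise (a much broader mixing
distribution bleeds admixed accessions into the parent clusters and the
five-cluster structure is no longer recoverable by any method).

**Genotypes.** At locus j, accession i carries the allele coded 1.0 with
probability p_ij = Σ_k q_ik f_kj. Rice accessions are selfing inbred
lines, so with probability `inbreeding` (default 0.99) the locus is
autozygous — dose = 2·Bernoulli(p_ij) — and otherwise Hardy–Weinberg,
dose ~ Binomial(2, p_ij). The numeric genotype is dose/2; calls are masked
missing independently at `missing_rate` (default 0.05). `inbreeding = 0`
recovers the plain binomial admixture model. The default of 0.99 mirrors
the ~1% residual heterozygosity of selfing germplasm and is what makes the
"all accessions homozygous" filter used by the discriminative-SNP stage
meaningful: under pure Hardy–Weinberg sampling at n = 300 essentially no
locus would survive it. One orientation is used everywhere: F is the
frequency of the allele coded 1.0 (the reference allele), and the VCF
writer converts numeric g to a reference dose of 2g.

**Phenotypes.** Accession genetic value ~ Normal(subpopulation mean,
σ²_G); each of r replicate records adds Normal(0, σ²_e) noise, so the
expected broad-sense heritability of accession means is
σ²_G/(σ²_G + σ²_e/r). Defaults: three traits (flowering time in days,
plant height in cm, grain length in mm), r = 4 replicates, subpopulation
means ordered so the admixed group is intermediate between its parents for
flowering time, and variance components giving h²_B between 0.94 and 0.96
— the high-heritability regime typical of these traits in replicated rice
trials.

**Default study conditions** (the `default_fixture`): K = 4 ancestors at
c = 0.3, five subpopulations sized (54, 45, 67, 92, 42) with the
45-accession group admixed between ancestors A and B, L = 5,000 SNPs.

**What the generator does not emulate:** linkage disequilibrium (loci are
independent given ancestry), within-subpopulation relatedness structure
(accessions are exchangeable within a group), selection, and read-level
genotyping-by-sequencing artifacts (missingness is uniform, not
coverage-driven). Passing recovery tests therefore demonstrate correctness
of the estimators under the admixture model itself, not robustness to LD
pruning choices, kinship confounding, or allele-specific genotyping error.

## Admixture fitting

The binomial admixture log-likelihood
ℓ(Q, F) = Σ_ij [2g_ij ln p_ij + 2(1 − g_ij) ln(1 − p_ij)] is maximized by
EM block updates (the classic alternating expected-allele-count updates),
which are monotone in ℓ — asserted per iteration in tests. Missing entries
contribute zero to the likelihood and to the update sums. Frequencies are
clamped to [1e-6, 1 − 1e-6] to guard log(0). Defaults: tol 1e-4 on the
log-likelihood change, max_iter 2,000, 3 seeded random restarts keeping
the best likelihood. EM is slow near the optimum, so runs typically stop
at max_iter rather than tol; Q is nevertheless recovered to mean absolute
error ≈ 0.007 on the default fixture within 300 iterations, and the
pipeline uses max_iter = 300 for the final fit and 200 inside elbow scans
(one restart per K there) as its standard desk-scale setting.

**Choosing K.** With gain(K) = ℓ(K) − ℓ(K−1), the elbow is the K
maximizing gain(K)/gain(K+1): the last K whose improvement dwarfs the
next. The ratio form is used rather than the difference gain(K) −
gain(K+1) because the difference is dominated by the raw scale of the
curve's steep region and systematically picks the shoulder below the true
elbow (on the default fixture geometry it prefers 4 clusters where the
generating structure has 5; the ratio criterion recovers both the K = 4
ancestor elbow and the k = 5 cluster elbow). When the range starts above
1, one extra fit below the range is run so every K except the maximum is a
candidate; gain(1) is measured against a one-parameter null (a single
shared allele frequency), which makes K = 1 win exactly when per-locus
frequency variation is the only structure — include K = 1 in the range
only to test for the absence of structure. The full ℓ(K) curve is always
emitted so the choice can be overridden.

**Ancestral F_ST.** Pairwise Hudson-type ratio of averages on the inferred
F rows: mean_j[(f_kj − f_lj)²] / mean_j[f_kj(1 − f_lj) + f_lj(1 − f_kj)],
zero diagonal, defined as 0 for identical fixed rows. Because the
estimator operates on inferred ancestral frequencies rather than sample
allele counts, values approximate rather than exactly reproduce what a
sample-based estimator would give.

## Clustering and bootstrap support

k-means (k-means++ seeding, 20 restarts, 300 iterations, Euclidean) on the
Q rows; the assignment minimizing within-cluster sum of squares wins. The
BCTSS ratio (TSS − WSS)/TSS is 0 for one cluster and 1 for perfect
separation, with 0 defined for degenerate all-identical input; k is chosen
by the same gain-ratio elbow on the BCTSS curve, with bctss(1) = 0 and one
extra evaluation above the range so the range maximum remains a candidate.

Cluster support formalizes "the likelihood that each cluster has the same
set of members" as clusterwise bootstrap stability: resample n accessions
with replacement, re-run k-means with the reference k, match each
reference cluster to the replicate cluster of maximal Jaccard similarity
over the resampled positions, and average that Jaccard value over
replicates (replicates where a cluster has no resampled member are skipped
and counted). Support is invariant to cluster relabeling. The package
default is 10,000 replicates; tests and the acceptance run use 200, which
already separates stable from unstable clusters cleanly at n = 300.
Resampling is over accessions (the unit the support table describes), not
loci.

## Structure summaries

PCA column-centers the numeric genotype matrix without unit-variance
scaling and decomposes by SVD; explained-variance fractions are relative
to the total variance of the centered matrix, and requesting components
beyond the rank truncates with a warning. Missing calls must be imputed
first; `impute_mean` substitutes locus means, which is adequate at the
≤ 30% missingness the call-rate filter guarantees.

The accession tree is classic Saitou–Nei neighbor joining on the 1 − IBS
distance (mean absolute numeric genotype difference, a metric on the
genotype coding). NJ is exact on additive distances — verified against
randomly generated ≤ 6-taxon trees — and negative branch lengths arising
from non-additivity are clamped to zero with a warning.

The origin association test is a Pearson chi-square of independence on the
origins × subpopulations count table (no continuity correction), dropping
all-zero rows/columns first; dof = (rows−1)(cols−1). The packaged
300-accession origin table gives dof 36 with p far below 0.01.

## Phenotype analysis

Variance components come from one-way random-effects ANOVA by method of
moments (σ̂²_e = MS_within; σ̂²_G = (MS_between − MS_within)/r floored at
0) rather than REML: it is closed-form, unbiased at the tested sample
sizes (bias < 0.02 at n = 500 across h² ∈ {0.5, 0.8, 0.95}), and checkable
by hand. Single-replicate designs are rejected (σ²_e inestimable);
unbalanced designs use the mean replicate count with a warning.

Domination graphs aggregate replicates to accession means first (the test
compares populations of accessions, avoiding plot-level
pseudo-replication), then run both one-sided Mann–Whitney tests per pair
and draw A→B iff p(A greater) ≤ α = 0.001. Both directions cannot pass at
α < 0.5, so the graph is antisymmetric by construction. No multiplicity
correction is applied across the pairs — α is a fixed per-test level, and
the measured family-wise false-edge rate over 1,000 null panels of five
groups is ≈ 0.014. The Mann–Whitney p is exact by enumeration when
min(n_x, n_y) ≤ 8 without ties and otherwise a tie-corrected normal
approximation with continuity correction; the two paths agree within 0.01
at the boundary.

## Discriminative SNP panels and classification

Scans run on loci where every non-missing call is homozygous (the natural
marker set for inbred material — heterozygous calls in selfing lines are
mostly artifacts or residual heterozygosity). Per locus, membership in the
target subpopulation (binary y) is regressed on genotype;
LOD = (n/2)·log10(RSS₀/RSS₁), capped at 50 when RSS₁ underflows (a
perfectly discriminating marker), 0 for monomorphic loci. Panels rank by
allele-frequency difference first and LOD second — both are reported so
the tie-break is auditable — taking up to 100 and at least 50 informative
loci per subpopulation (fewer triggers a warning and takes all), then
deduplicate the union, attributing each locus to the subpopulation ranking
it highest.

Gene overlay: a locus hits a gene when its position lies in the gene's
1-based inclusive [start, end], strand-agnostic; additionally, runs of
panel SNPs with inter-SNP gaps ≤ 100 kb report every gene overlapping the
run's span, mirroring how clusters of predictive SNPs delimit candidate
intervals.

Classification uses stratified k-fold cross-validation (default 10 folds,
seeded shuffling) with a random-forest default behind a pluggable
fit/predict estimator contract — the scientific surface is the CV protocol
and the per-class one-vs-rest metrics, not the tree implementation.
Missing panel genotypes are mean-imputed from the training folds only, so
no information leaks from test folds. Precision, recall and F1 =
2PR/(P+R) (0 when P + R = 0) are computed from pooled out-of-fold
predictions; every accession is scored exactly once.

## Problem sizes and runtime choices

The package's standard desk-scale run — used by the test suite and the
acceptance script — is the default fixture (n = 300, L = 5,000), EM at
max_iter 300 with 3 restarts for the final fit, elbow scans over K = 2–7
and k = 2–8, 200 bootstrap replicates, 10-fold CV, 1,000 null panels for
calibration. The whole analysis completes in a few minutes on one CPU.
All randomness flows from per-stage seeds derived from a single master
seed, and identical seeds give bit-identical outputs (asserted for the
full artifact set).

## Known limitations

- EM convergence is first-order; with tol = 1e-4 the iteration cap is the
  effective stopping rule, and log-likelihoods are comparable across K
  only when fitted with the same cap.
- The gain-ratio elbow assumes a single dominant scale break in the curve;
  data with hierarchical structure at several scales can produce ambiguous
  ratios, which is why both elbow routines always emit the full curve.
- Bootstrap support is computed against a fixed reference clustering; it
  measures stability of that reference, not global cluster validity.
- The 1 − IBS distance ignores allele-frequency weighting; rare-allele
  sharing and common-allele sharing count equally.
- Panel selection scores loci marginally; linked loci carrying redundant
  signal are not pruned, so panel sizes overstate the number of
  independent markers.
- The chi-square test uses the asymptotic distribution; several cells of a
  sparse origin table can have small expected counts, and the expected
  counts are exposed for that diagnostic purpose.
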