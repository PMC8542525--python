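# ricepop

Population-structure analysis for nation-wide rice germplasm panels.

Rice breeding programs maintain hundreds of accessions — distinct inbred
varieties collected across a country's growing regions. Before any
association study or marker-assisted selection, one needs to know the
panel's population structure: how many ancestral gene pools contributed to
it, which accessions are admixed, how the inferred subpopulations relate to
geographic origin and to phenotypes, and whether a small SNP panel suffices
to assign a new accession to its subpopulation. `ricepop` implements that
whole workflow for numeric bi-allelic genotype matrices, together with a
synthetic data generator with known truth so that every stage is testable
by parameter recovery.

## The models

**Numeric genotypes.** Diploid calls are coded 1.0 (homozygous reference),
0.5 (heterozygous), 0.0 (homozygous alternate); SNPs are filtered at
minor-allele frequency ≥ 0.05 and call rate ≥ 70% per SNP.

**Admixture model.** Accession *i* carries two alleles per locus *j* drawn
with reference-allele probability p<sub>ij</sub> = Σ<sub>k</sub>
q<sub>ik</sub> f<sub>kj</sub>, where Q (n×K) holds per-accession ancestry
ratios over K ancestral populations and F (K×L) the ancestral allele
frequencies. The binomial log-likelihood
ℓ(Q, F) = Σ<sub>ij</sub> [2g<sub>ij</sub> ln p<sub>ij</sub> + 2(1 −
g<sub>ij</sub>) ln(1 − p<sub>ij</sub>)] is maximized by monotone EM block
updates with seeded restarts; K is chosen by the elbow of ℓ(K). Divergence
between ancestors is summarized by pairwise Hudson F<sub>ST</sub> on the F
rows.

**Subpopulations.** Accessions are k-means-clustered on their Q rows; k is
chosen by the elbow of the between-cluster / total sum-of-squares (BCTSS)
ratio, and each cluster receives a bootstrap support — the mean Jaccard
similarity between the cluster and its best match across re-clusterings of
accession resamples. Admixed groups show up as the least-supported cluster.

**Structure summaries.** PCA of the column-centered genotype matrix,
neighbor-joining tree on 1 − IBS distances (newick output), and a Pearson
chi-square test of independence between geographic origin and
subpopulation.

**Phenotypes.** Broad-sense heritability of accession means from replicated
trials, h²<sub>B</sub> = σ²<sub>G</sub>/(σ²<sub>G</sub> + σ²<sub>e</sub>/r),
with variance components from one-way random-effects ANOVA; per-trait
domination graphs draw an edge from subpopulation A to B when A's values
are stochastically greater by a one-sided Mann–Whitney test at α = 0.001.

**Discriminative SNPs.** Per subpopulation, membership is scanned as a
binary trait against every homozygous bi-allelic locus (single-marker
regression LOD plus in/out allele-frequency difference); the top 50–100
loci per subpopulation are unioned into a compact panel, overlaid with GFF3
gene annotations, and evaluated by stratified 10-fold cross-validated
classification (per-class precision, recall, F1 = 2PR/(P+R)).

## Worked example

```python
from ricepop import (default_fixture, filter_maf_callrate, AdmixtureModel,
                     select_k_elbow, kmeans_cluster, bootstrap_support)

G, pheno, truth = default_fixture(seed=1)          # 300 accessions, 5,000 SNPs
Gf = filter_maf_callrate(G, maf_min=0.05, callrate_min=0.70)
print(f"{G.n_loci} -> {Gf.n_loci} loci after MAF/call-rate filtering")

fit = AdmixtureModel(Gf, K=4).fit(seed=1, max_iter=300)
print(fit.summary())

k = select_k_elbow(fit.Q, range(2, 9), seed=5)     # BCTSS elbow
clusters = kmeans_cluster(fit.Q, k, seed=5)
bootstrap_support(fit.Q, clusters, n_boot=200, seed=6)
print(clusters.support_table().to_string(index=False))
```

prints

```
5000 -> 4710 loci after MAF/call-rate filtering
Admixture model results
===============================================
ancestors (K):       4
accessions:          300
loci:                4710
log-likelihood:      -1200641.390
converged:           False (300 iterations)
mean ancestry ratio: 0.305  0.145  0.254  0.296
pairwise ancestral FST: (1,2)=0.313  (1,3)=0.315  (1,4)=0.317  (2,3)=0.313  (2,4)=0.316  (3,4)=0.314
population  n_accessions  support
      POP1            44   0.9881
      POP2            42   1.0000
      POP3            92   1.0000
      POP4            55   0.9910
      POP5            67   0.9998
```

The synthetic panel was generated at pairwise ancestral F<sub>ST</sub>
c = 0.3; the fitted ancestral divergences land on ≈ 0.31, the BCTSS elbow
recovers five subpopulations from four ancestors, and the least-supported
cluster (POP1 here, support 0.988) is the admixed group — the signature an
admixed population leaves in real panels. The three bundled traits have
generating broad-sense heritabilities above 0.94 and subpopulation-specific
means, so domination graphs and heritability estimates are recoverable
downstream.

The same stages run from the shell:

```bash
ricepop simulate --seed 1 --out-prefix syn
ricepop filter syn.vcf syn.filtered.vcf
ricepop ancestry syn.filtered.vcf --seed 1
ricepop cluster ancestry.Q --n-boot 200 --seed 5
ricepop run-all --seed 1 --outdir out/       # everything, with a manifest
```

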