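"""Shared fixtures: one full-scale synthetic study run, computed once.

The session fixture mirrors the package's default study conditions (300
accessions, K=4 ancestors at c=0.3, five subpopulations with the second
admixed, 5,000 loci) and runs every pipeline stage; recovery and pattern
tests share it instead of refitting.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from ricepop.simulate import default_fixture
from ricepop.genotypes import filter_maf_callrate, filter_biallelic_homozygous
from ricepop.admixture import AdmixtureModel, select_K_elbow
from ricepop.clustering import kmeans_cluster, select_k_elbow, bootstrap_support
from ricepop.panel import one_vs_rest_scan, select_panel, crossval_classify

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    G, pheno, truth = default_fixture(seed=STUDY_SEED)
    Gf = filter_maf_callrate(G)
    K, K_curve = select_K_elbow(Gf, range(2, 8), seed=7, return_curve=True)
    fit = AdmixtureModel(Gf, K).fit(seed=STUDY_SEED, max_iter=300, n_restarts=3)
    k, k_curve = select_k_elbow(fit.Q, range(2, 9), seed=5, return_curve=True)
    clusters = kmeans_cluster(fit.Q, k, seed=5)
    support = bootstrap_support(fit.Q, clusters, n_boot=200, seed=6)
    Gh = filter_biallelic_homozygous(Gf)
    scans = {c: one_vs_rest_scan(Gh, clusters.labels, c)
             for c in sorted(np.unique(clusters.labels))}
    panel = select_panel(scans)
    key = {(c, p): j for j, (c, p) in
           enumerate(zip(Gh.loci["chrom"], Gh.loci["pos"]))}
    cols = [key[(r.chrom, r.pos)] for r in panel.loci.itertuples(index=False)]
    cv = crossval_classify(Gh.take_loci(cols), clusters.labels, folds=10,
                           seed=3)
    # admixed subpopulation index is 1 (0-based) by construction; find the
    # cluster label that carries it
    admixed_cluster = None
    best_overlap = -1
    for c in range(1, clusters.k + 1):
        overlap = int(np.sum((clusters.labels == c) & (truth.true_labels == 1)))
        if overlap > best_overlap:
            best_overlap, admixed_cluster = overlap, c
    return SimpleNamespace(G=G, Gf=Gf, Gh=Gh, pheno=pheno, truth=truth,
                           K=K, K_curve=K_curve, fit=fit, k=k, k_curve=k_curve,
                           clusters=clusters, support=support, scans=scans,
                           panel=panel, cv=cv, admixed_cluster=admixed_cluster)
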