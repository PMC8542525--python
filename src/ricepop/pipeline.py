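"""Configuration-driven orchestration of the full analysis.

A :class:`PipelineConfig` (YAML-loadable) describes either a synthetic
panel to simulate or input files to ingest, plus every stage threshold and
seed.  :func:`run_pipeline` executes encoding -> filtering -> ancestry ->
clustering -> summaries -> phenotypes -> panel -> cross-validation, writes
every intermediate artifact as plain text (CSV/TSV/VCF/newick/DOT) and a
JSON manifest of seeds, parameters and artifact paths.  Re-running the same
config reproduces all numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (GenotypeMatrix, read_vcf, write_vcf, read_tsv,
                        filter_maf_callrate, filter_biallelic_homozygous,
                        impute_mean)
from .admixture import AdmixtureModel, select_K_elbow
from .clustering import kmeans_cluster, select_k_elbow, bootstrap_support
from .summaries import (pca, distance_matrix, nj_tree, contingency_table,
                        origin_association_test)
from .phenotypes import broad_sense_heritability, domination_graph, read_traits_csv
from .panel import one_vs_rest_scan, select_panel, annotate_genes, crossval_classify
from . import simulate as sim

log = logging.getLogger("ricepop")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline inputs, thresholds and seeds.

    Either ``synthetic=True`` (simulate the default panel) or paths to a
    VCF/TSV genotype file, a labels CSV and a traits CSV.
    """

    outdir: str = "ricepop_out"
    # inputs
    synthetic: bool = True
    vcf: str = None
    genotype_tsv: str = None
    traits_csv: str = None
    origins_csv: str = None
    gff3: str = None
    # synthetic spec
    n_loci: int = 5000
    fst: float = 0.3
    missing_rate: float = 0.05
    inbreeding: float = 0.99
    replicates: int = 4
    # thresholds
    maf_min: float = 0.05
    callrate_min: float = 0.70
    alpha: float = 0.001
    per_pop_min: int = 50
    per_pop_max: int = 100
    folds: int = 10
    n_boot: int = 10000
    K_range: list = field(default_factory=lambda: list(range(2, 8)))
    k_range: list = field(default_factory=lambda: list(range(2, 9)))
    K: int = None            # override elbow choice
    k: int = None
    em_max_iter: int = 300
    em_restarts: int = 3
    elbow_max_iter: int = 200
    # seeds per stage
    seed: int = 0
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, val, lo, hi in (("maf_min", self.maf_min, 0, 1),
                                  ("callrate_min", self.callrate_min, 0, 1),
                                  ("alpha", self.alpha, 0, 0.5)):
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if self.per_pop_min > self.per_pop_max:
            raise ValueError("per_pop_min must be <= per_pop_max")
        defaults = {}
        ss = np.random.SeedSequence(self.seed)
        stages = ["simulate", "ancestry", "elbow_K", "cluster", "elbow_k",
                  "bootstrap", "cv", "origins"]
        for stage, child in zip(stages, ss.spawn(len(stages))):
            defaults[stage] = int(child.generate_state(1)[0] % (2**31))
        defaults.update(self.seeds or {})
        self.seeds = defaults

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write(df: pd.DataFrame, path: Path, **kw):
    df.to_csv(path, index=kw.pop("index", False), **kw)
    return str(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest dict.

    Artifacts: filtered genotype VCF, Q/F matrices, cluster labels +
    support table, BCTSS curve, PCA scores, newick tree, chi-square report,
    heritability table, domination edge lists, panel TSV, CV report, and
    ``manifest.json``.  A stage failure raises with the stage named;
    artifacts of completed stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seeds": config.seeds,
                "parameters": {key: val for key, val in asdict(config).items()
                               if key != "seeds"},
                "stages": {}, "artifacts": {}}
    t_start = time.time()
    stage = "simulate/ingest"
    try:
        truth = None
        if config.synthetic:
            G, pheno, truth = sim.default_fixture(
                seed=config.seeds["simulate"], n_loci=config.n_loci,
                fst=config.fst, missing_rate=config.missing_rate,
                inbreeding=config.inbreeding, r=config.replicates)
            origins = sim.simulate_origins(truth.true_labels,
                                           seed=config.seeds["origins"])
            write_vcf(G, out / "genotypes.vcf")
            manifest["artifacts"]["genotypes_vcf"] = str(out / "genotypes.vcf")
            sim.write_traits_csv(pheno, out / "traits.csv")
            manifest["artifacts"]["traits_csv"] = str(out / "traits.csv")
            gff_path = out / "genes.gff3"
            sim.write_synthetic_gff3(G.loci, gff_path,
                                     seed=config.seeds["simulate"])
            manifest["artifacts"]["gff3"] = str(gff_path)
        else:
            if config.vcf:
                G = read_vcf(config.vcf)
            elif config.genotype_tsv:
                G = read_tsv(config.genotype_tsv)
            else:
                raise ValueError("no genotype input configured")
            pheno = read_traits_csv(config.traits_csv) if config.traits_csv else None
            origins = None
            if config.origins_csv:
                odf = pd.read_csv(config.origins_csv)
                origins = odf.set_index("accession_id")["origin"].reindex(
                    G.accession_ids).tolist()
            gff_path = config.gff3
        manifest["stages"][stage] = {"n_accessions": G.n_accessions,
                                     "n_loci": G.n_loci}

        stage = "filter"
        Gf = filter_maf_callrate(G, config.maf_min, config.callrate_min)
        write_vcf(Gf, out / "genotypes.filtered.vcf")
        manifest["artifacts"]["filtered_vcf"] = str(out / "genotypes.filtered.vcf")
        manifest["stages"][stage] = {"loci_before": G.n_loci,
                                     "loci_after": Gf.n_loci}
        log.info("filter: %d -> %d loci", G.n_loci, Gf.n_loci)

        stage = "ancestry"
        if config.K is None:
            K, curve = select_K_elbow(Gf, config.K_range,
                                      seed=config.seeds["elbow_K"],
                                      max_iter=config.elbow_max_iter,
                                      return_curve=True)
            _write(pd.DataFrame({"K": list(curve), "loglik": list(curve.values())}),
                   out / "elbow_K.csv")
            manifest["artifacts"]["elbow_K_csv"] = str(out / "elbow_K.csv")
        else:
            K = config.K
        fit = AdmixtureModel(Gf, K).fit(seed=config.seeds["ancestry"],
                                        max_iter=config.em_max_iter,
                                        n_restarts=config.em_restarts)
        fit.save(out / "ancestry.Q", out / "ancestry.P")
        manifest["artifacts"]["Q"] = str(out / "ancestry.Q")
        manifest["artifacts"]["P"] = str(out / "ancestry.P")
        fst = fit.ancestral_fst()
        _write(pd.DataFrame(fst, columns=[f"anc{i+1}" for i in range(K)]),
               out / "ancestral_fst.csv")
        manifest["artifacts"]["ancestral_fst_csv"] = str(out / "ancestral_fst.csv")
        manifest["stages"][stage] = {"K": K, "loglik": fit.loglik,
                                     "converged": bool(fit.converged)}

        stage = "cluster"
        if config.k is None:
            k, kcurve = select_k_elbow(fit.Q, config.k_range,
                                       seed=config.seeds["elbow_k"],
                                       return_curve=True)
            _write(pd.DataFrame({"k": list(kcurve),
                                 "bctss": list(kcurve.values())}),
                   out / "elbow_k_bctss.csv")
            manifest["artifacts"]["bctss_curve_csv"] = str(out / "elbow_k_bctss.csv")
        else:
            k = config.k
        ca = kmeans_cluster(fit.Q, k, seed=config.seeds["cluster"])
        bootstrap_support(fit.Q, ca, n_boot=config.n_boot,
                          seed=config.seeds["bootstrap"])
        sim.write_labels_csv(Gf.accession_ids, ca.labels - 1,
                             out / "subpopulations.csv")
        manifest["artifacts"]["labels_csv"] = str(out / "subpopulations.csv")
        _write(ca.support_table(), out / "cluster_support.csv")
        manifest["artifacts"]["support_csv"] = str(out / "cluster_support.csv")
        manifest["stages"][stage] = {"k": k, "bctss": ca.bctss,
                                     "support": ca.support.tolist()}

        stage = "summaries"
        Gc = impute_mean(Gf)
        pc = pca(Gc, m=5)
        _write(pc.to_frame(Gf.accession_ids), out / "pca_scores.csv", index=True)
        manifest["artifacts"]["pca_csv"] = str(out / "pca_scores.csv")
        D = distance_matrix(Gc)
        nwk = nj_tree(D, Gf.accession_ids)
        (out / "nj_tree.nwk").write_text(nwk + "\n")
        manifest["artifacts"]["newick"] = str(out / "nj_tree.nwk")
        chi_info = None
        if origins is not None:
            T = contingency_table(origins, ca.labels)
            res = origin_association_test(T)
            chi_info = {"chi2": res.chi2, "dof": res.dof, "p": res.p}
            _write(T, out / "origin_by_subpop.csv", index=True)
            (out / "chi_square.json").write_text(json.dumps(chi_info, indent=1))
            manifest["artifacts"]["chi_square_json"] = str(out / "chi_square.json")
        manifest["stages"][stage] = {"pca_var": pc.explained_variance.tolist(),
                                     "chi_square": chi_info}

        stage = "phenotypes"
        herit_rows, dom_paths = [], {}
        if pheno is not None:
            label_map = pd.Series(ca.labels, index=Gf.accession_ids)
            for trait in sorted(pheno["trait"].unique()):
                h2 = broad_sense_heritability(pheno, trait)
                herit_rows.append({"trait": trait, "h2_broad_sense": h2})
                dg = domination_graph(pheno, label_map, trait,
                                      alpha=config.alpha)
                _write(dg.edges, out / f"domination_{trait}.csv")
                (out / f"domination_{trait}.dot").write_text(dg.to_dot() + "\n")
                dom_paths[trait] = str(out / f"domination_{trait}.csv")
            _write(pd.DataFrame(herit_rows), out / "heritability.csv")
            manifest["artifacts"]["heritability_csv"] = str(out / "heritability.csv")
            manifest["artifacts"]["domination_csvs"] = dom_paths
        manifest["stages"][stage] = {"heritability": herit_rows}

        stage = "panel"
        Gh = filter_biallelic_homozygous(Gf)
        scans = {c: one_vs_rest_scan(Gh, ca.labels, c)
                 for c in sorted(np.unique(ca.labels))}
        panel = select_panel(scans, config.per_pop_min, config.per_pop_max)
        panel.to_tsv(out / "panel.tsv")
        manifest["artifacts"]["panel_tsv"] = str(out / "panel.tsv")
        gene_info = None
        if gff_path:
            hits, intervals = annotate_genes(panel, gff_path)
            _write(hits, out / "panel_gene_hits.tsv", sep="\t")
            _write(intervals, out / "panel_interval_genes.tsv", sep="\t")
            manifest["artifacts"]["gene_hits_tsv"] = str(out / "panel_gene_hits.tsv")
            manifest["artifacts"]["interval_genes_tsv"] = str(
                out / "panel_interval_genes.tsv")
            gene_info = {"snps_in_genes": int(hits["pos"].nunique()),
                         "genes_hit": int(hits["gene_id"].nunique())}
        manifest["stages"][stage] = {"homozygous_loci": Gh.n_loci,
                                     "panel_size": panel.size,
                                     "genes": gene_info}

        stage = "classify"
        key = {(c, p): j for j, (c, p) in
               enumerate(zip(Gh.loci["chrom"], Gh.loci["pos"]))}
        cols = [key[(r.chrom, r.pos)] for r in panel.loci.itertuples(index=False)]
        report = crossval_classify(Gh.take_loci(cols), ca.labels,
                                   folds=config.folds, seed=config.seeds["cv"])
        report.to_csv(out / "cv_report.csv")
        manifest["artifacts"]["cv_report_csv"] = str(out / "cv_report.csv")
        manifest["stages"][stage] = {
            "folds": report.folds,
            "per_class_f1": report.metrics["f1"].round(4).to_dict()}
    except Exception as err:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["runtime_seconds"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    manifest["artifacts"]["manifest"] = str(out / "manifest.json")
    return manifest
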