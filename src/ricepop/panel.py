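"""Discriminative SNP panels and panel-based population classification.

For each subpopulation, membership is treated as a binary trait (same
population vs other populations) and every homozygous bi-allelic locus is
scored by single-marker linear regression: LOD = (n/2) log10(RSS0 / RSS1)
with RSS0 the intercept-only residual sum of squares, together with the
in/out allele-frequency difference.  The per-population top loci (ranked by
frequency difference, then LOD) are unioned into a compact panel, gene
annotations are overlaid from a GFF3, and panel-based assignment of
accessions to subpopulations is evaluated by stratified k-fold
cross-validation with per-class precision, recall and F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["ScanResult", "one_vs_rest_scan", "DiscriminativePanel",
           "select_panel", "annotate_genes", "CVReport", "crossval_classify"]

LOD_CAP = 50.0  # cap when RSS1 underflows (perfect marker)


@dataclass
class ScanResult:
    """Per-locus one-vs-rest scan scores for one target subpopulation."""

    target_pop: object
    table: pd.DataFrame  # columns: chrom, pos, lod, allele_freq_diff

    def top(self, m: int) -> pd.DataFrame:
        return self.table.sort_values(
            ["allele_freq_diff", "lod"], ascending=False, kind="mergesort"
        ).head(m)


def one_vs_rest_scan(G: GenotypeMatrix, labels, target_pop) -> ScanResult:
    """Score every locus for discriminating ``target_pop`` from the rest.

    ``G`` should already be restricted to all-homozygous bi-allelic loci.
    Missing calls are dropped per locus.  Monomorphic loci get LOD 0; a
    perfect fit (RSS1 ~ 0) is capped at LOD_CAP.
    """
    labels = np.asarray(labels)
    if target_pop not in labels:
        raise ValueError(f"target population {target_pop!r} absent from labels")
    y = (labels == target_pop).astype(float)
    V = G.values
    mask = ~np.isnan(V)
    Vz = np.where(mask, V, 0.0)
    n = mask.sum(axis=0).astype(float)                       # calls per locus
    sy = mask.T @ y
    syy = mask.T @ (y ** 2)
    sg = Vz.sum(axis=0)
    sgg = (Vz ** 2).sum(axis=0)
    sgy = Vz.T @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = syy - sy ** 2 / n
        sxx = sgg - sg ** 2 / n
        sxy = sgy - sg * sy / n
        rss1 = rss0 - np.where(sxx > 1e-12, sxy ** 2 / np.maximum(sxx, 1e-300), 0.0)
        lod = np.where(
            rss1 > 1e-12,
            (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1),
            np.where(rss0 > 1e-12, LOD_CAP, 0.0),
        )
    lod = np.clip(np.where(np.isfinite(lod), lod, 0.0), 0.0, LOD_CAP)
    # in/out allele frequencies on non-missing calls
    in_mask = mask * y[:, None]
    out_mask = mask * (1.0 - y)[:, None]
    with np.errstate(invalid="ignore"):
        p_in = (Vz * y[:, None]).sum(axis=0) / in_mask.sum(axis=0)
        p_out = (Vz * (1.0 - y)[:, None]).sum(axis=0) / out_mask.sum(axis=0)
    diff = np.abs(p_in - p_out)
    diff = np.where(np.isfinite(diff), diff, 0.0)
    table = pd.DataFrame({
        "chrom": G.loci["chrom"].to_numpy(),
        "pos": G.loci["pos"].to_numpy(),
        "lod": lod,
        "allele_freq_diff": diff,
    })
    return ScanResult(target_pop=target_pop, table=table)


@dataclass
class DiscriminativePanel:
    """Per-population ranked discriminative loci and their deduplicated union."""

    per_pop: dict            # pop -> DataFrame (chrom, pos, allele_freq_diff, lod)
    loci: pd.DataFrame       # union: chrom, pos, best_for, allele_freq_diff, lod
    per_pop_min: int
    per_pop_max: int

    @property
    def size(self) -> int:
        return len(self.loci)

    def to_tsv(self, path) -> None:
        rows = []
        for pop, tab in self.per_pop.items():
            t = tab.copy()
            t.insert(0, "population", pop)
            rows.append(t)
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def select_panel(scans: dict, per_pop_min: int = 50,
                 per_pop_max: int = 100) -> DiscriminativePanel:
    """Assemble the discriminative panel from per-population scans.

    Per population, loci are ranked lexicographically by (allele frequency
    difference, LOD) descending and the top ``per_pop_max`` with positive
    frequency difference are taken; fewer than ``per_pop_min`` informative
    loci triggers a warning and takes all.  The union is deduplicated by
    (chrom, pos); each union locus records the population whose scan ranks
    it highest ("most predictive for").
    """
    if per_pop_min > per_pop_max:
        raise ValueError("per_pop_min must be <= per_pop_max")
    per_pop = {}
    best = {}
    for pop, scan in scans.items():
        tab = scan.table.sort_values(["allele_freq_diff", "lod"],
                                     ascending=False, kind="mergesort")
        tab = tab.loc[tab["allele_freq_diff"] > 0]
        if len(tab) < per_pop_min:
            warnings.warn(f"population {pop!r}: only {len(tab)} informative "
                          f"loci (< {per_pop_min}); taking all")
        sel = tab.head(per_pop_max).reset_index(drop=True)
        per_pop[pop] = sel
        for rank, row in enumerate(sel.itertuples(index=False)):
            key = (row.chrom, row.pos)
            score = (row.allele_freq_diff, row.lod)
            if key not in best or score > best[key][0]:
                best[key] = (score, pop, row.allele_freq_diff, row.lod)
    if not best:
        warnings.warn("no informative loci in any scan; panel is empty")
    union = pd.DataFrame(
        [(c, p, v[1], v[2], v[3]) for (c, p), v in sorted(best.items())],
        columns=["chrom", "pos", "best_for", "allele_freq_diff", "lod"])
    return DiscriminativePanel(per_pop=per_pop, loci=union,
                               per_pop_min=per_pop_min, per_pop_max=per_pop_max)


def annotate_genes(panel: DiscriminativePanel, gff_path,
                   interval_window: int = 100_000):
    """Overlay GFF3 gene annotations on the panel.

    Returns ``(hits, interval_genes)``: per-locus gene containment (1-based
    inclusive intervals, strand-agnostic), and the genes overlapping the
    span of each run of panel SNPs on one chromosome whose inter-SNP gaps
    are <= ``interval_window``.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), dbfn=":memory:",
                            merge_strategy="create_unique", force=True)
    genes = [f for f in db.all_features(featuretype="gene")]
    gene_tab = pd.DataFrame({
        "seqid": [g.seqid for g in genes],
        "start": [g.start for g in genes],
        "end": [g.end for g in genes],
        "gene_id": [g.id for g in genes],
    })
    hit_rows = []
    for row in panel.loci.itertuples(index=False):
        sel = gene_tab.loc[(gene_tab["seqid"] == str(row.chrom)) &
                           (gene_tab["start"] <= row.pos) &
                           (gene_tab["end"] >= row.pos)]
        for g in sel.itertuples(index=False):
            hit_rows.append((row.chrom, row.pos, g.gene_id, g.start, g.end))
    hits = pd.DataFrame(hit_rows,
                        columns=["chrom", "pos", "gene_id", "gene_start",
                                 "gene_end"])
    run_rows = []
    for chrom, block in panel.loci.groupby("chrom"):
        pos = np.sort(block["pos"].to_numpy())
        run_start = pos[0]
        prev = pos[0]
        run_id = 0
        spans = []
        for p in pos[1:]:
            if p - prev > interval_window:
                spans.append((run_start, prev))
                run_start = p
            prev = p
        spans.append((run_start, prev))
        for start, end in spans:
            run_id += 1
            sel = gene_tab.loc[(gene_tab["seqid"] == str(chrom)) &
                               (gene_tab["start"] <= end) &
                               (gene_tab["end"] >= start)]
            for g in sel.itertuples(index=False):
                run_rows.append((chrom, f"{chrom}:{start}-{end}", g.gene_id))
    interval_genes = pd.DataFrame(run_rows,
                                  columns=["chrom", "interval", "gene_id"])
    return hits, interval_genes


@dataclass
class CVReport:
    """Cross-validated per-class classification metrics."""

    metrics: pd.DataFrame      # index: class; precision, recall, f1
    confusion: pd.DataFrame    # true x predicted counts
    folds: int
    seed: int

    def to_csv(self, path) -> None:
        out = self.metrics.round(4)
        out.index.name = "class"
        out.to_csv(path)


def crossval_classify(G_panel, labels, folds: int = 10, seed: int = 0,
                      estimator=None) -> CVReport:
    """Stratified k-fold cross-validated population assignment.

    ``G_panel`` is the accessions x panel-loci numeric matrix (missing
    allowed: imputation uses training-fold locus means only).  The default
    classifier is a random forest; any estimator with fit/predict can be
    plugged in (cloned per fold).  Pooled out-of-fold predictions are
    scored per class with one-vs-rest TP/FP/FN counts:
    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2 * precision * recall / (precision + recall) (0 when the
    denominator is 0).
    """
    from sklearn.base import clone
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    X = G_panel.values if isinstance(G_panel, GenotypeMatrix) else np.asarray(
        G_panel, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        new_folds = int(counts.min())
        warnings.warn(f"smallest class has {counts.min()} members; reducing "
                      f"folds {folds} -> {new_folds}")
        folds = new_folds
    if folds < 2:
        raise ValueError("need at least 2 folds (and >= 2 members per class)")
    if estimator is None:
        estimator = RandomForestClassifier(n_estimators=200, random_state=seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < len(classes):
            raise ValueError("a class is absent from a training fold; use "
                             "fewer folds")
        Xtr, Xte = X[train].copy(), X[test].copy()
        mu = np.nanmean(Xtr, axis=0)
        mu = np.where(np.isnan(mu), 0.5, mu)
        for M in (Xtr, Xte):
            miss = np.isnan(M)
            if miss.any():
                M[miss] = np.broadcast_to(mu, M.shape)[miss]
        clf = clone(estimator)
        clf.fit(Xtr, y[train])
        pred[test] = clf.predict(Xte)
    conf = pd.crosstab(pd.Series(y, name="true"),
                       pd.Series(pred, name="predicted")).reindex(
        index=classes, columns=classes, fill_value=0)
    rows = {}
    for c in classes:
        tp = int(conf.loc[c, c])
        fp = int(conf[c].sum()) - tp
        fn = int(conf.loc[c].sum()) - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        rows[c] = {"precision": prec, "recall": rec, "f1": f1}
    metrics = pd.DataFrame(rows).T.loc[classes]
    return CVReport(metrics=metrics, confusion=conf, folds=folds, seed=seed)
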