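"""One-vs-rest SNP scans, panel assembly, gene overlay and cross-validated
population classification."""

import numpy as np
import pandas as pd
import pytest

from ricepop.genotypes import GenotypeMatrix
from ricepop.panel import (LOD_CAP, annotate_genes, crossval_classify,
                           one_vs_rest_scan, select_panel)


def _matrix(vals, chrom=None, pos=None):
    vals = np.array(vals, dtype=float)
    loci = None
    if pos is not None:
        loci = pd.DataFrame({"chrom": chrom or ["1"] * len(pos), "pos": pos,
                             "ref": "A", "alt": "T"})
    return GenotypeMatrix(vals, loci=loci)


class TestScan:
    def test_perfect_marker_capped_lod_and_full_freq_diff(self):
        vals = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])
        G = _matrix(vals)
        labels = np.array([1, 1, 1, 2, 2, 2])
        scan = one_vs_rest_scan(G, labels, 1)
        assert scan.table["allele_freq_diff"].iloc[0] == pytest.approx(1.0)
        assert scan.table["lod"].iloc[0] == LOD_CAP

    def test_uninformative_locus_zero_scores(self):
        vals = np.array([[1.0], [0.0], [1.0], [0.0]])
        G = _matrix(vals)
        labels = np.array([1, 1, 2, 2])
        scan = one_vs_rest_scan(G, labels, 1)
        assert scan.table["allele_freq_diff"].iloc[0] == pytest.approx(0.0)
        assert scan.table["lod"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_monomorphic_locus_lod_zero(self):
        vals = np.ones((6, 1))
        labels = np.array([1, 1, 1, 2, 2, 2])
        scan = one_vs_rest_scan(_matrix(vals), labels, 1)
        assert scan.table["lod"].iloc[0] == 0.0
        assert scan.table["allele_freq_diff"].iloc[0] == 0.0

    def test_lod_matches_least_squares_oracle(self):
        """12-accession toy: LOD from the implementation equals the direct
        normal-equation solve to 1e-9."""
        rng = np.random.default_rng(0)
        vals = rng.choice([0.0, 1.0], size=(12, 8))
        vals[2, 3] = np.nan
        labels = np.array([1] * 5 + [2] * 7)
        scan = one_vs_rest_scan(_matrix(vals), labels, 1)
        y_all = (labels == 1).astype(float)
        for j in range(8):
            g = vals[:, j]
            m = ~np.isnan(g)
            y, gj = y_all[m], g[m]
            n = m.sum()
            rss0 = float(((y - y.mean()) ** 2).sum())
            X = np.column_stack([np.ones(n), gj])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(((y - X @ beta) ** 2).sum())
            if rss1 > 1e-12:
                expected = (n / 2) * np.log10(rss0 / rss1)
                expected = min(expected, LOD_CAP)
            else:
                expected = LOD_CAP if rss0 > 1e-12 else 0.0
            assert scan.table["lod"].iloc[j] == pytest.approx(expected,
                                                              abs=1e-9)

    def test_missing_target_pop_rejected(self):
        G = _matrix(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="absent"):
            one_vs_rest_scan(G, np.array([1, 1, 2, 2]), 9)


class TestSelectPanel:
    def _fixed_diff_matrix(self, n_per=6, n_loci_each=60):
        """Populations 1 and 2 each privately fixed at a disjoint locus
        block against a third background population."""
        L = 2 * n_loci_each
        vals = np.zeros((3 * n_per, L))
        vals[:n_per, :n_loci_each] = 1.0             # pop 1's private block
        vals[n_per:2 * n_per, n_loci_each:] = 1.0    # pop 2's private block
        pos = np.arange(1, L + 1) * 1000
        labels = np.array([1] * n_per + [2] * n_per + [3] * n_per)
        return _matrix(vals, pos=pos), labels

    def test_disjoint_fixed_blocks_give_expected_panel(self):
        G, labels = self._fixed_diff_matrix()
        scans = {p: one_vs_rest_scan(G, labels, p) for p in (1, 2)}
        panel = select_panel(scans, per_pop_min=50, per_pop_max=60)
        assert panel.size == 120
        counts = panel.loci["best_for"].value_counts()
        assert counts[1] == 60 and counts[2] == 60

    def test_identical_populations_empty_panel(self):
        # same genotype row everywhere: no locus discriminates anything
        vals = np.tile([[1.0, 0.0, 1.0, 0.0, 1.0]], (6, 1))
        G = _matrix(vals)
        labels = np.array([1, 2] * 3)
        scans = {p: one_vs_rest_scan(G, labels, p) for p in (1, 2)}
        with pytest.warns(UserWarning):
            panel = select_panel(scans)
        assert panel.size == 0

    def test_shared_locus_deduplicated(self):
        G, labels = self._fixed_diff_matrix(n_per=4, n_loci_each=3)
        scans = {p: one_vs_rest_scan(G, labels, p) for p in (1, 2)}
        panel = select_panel(scans, per_pop_min=3, per_pop_max=6)
        # every locus discriminates both populations (diff 1 for each scan)
        # so both scans select all 6 loci; the union holds each once
        assert panel.size == 6
        assert panel.loci.duplicated(["chrom", "pos"]).sum() == 0

    def test_invariant_to_locus_order(self):
        G, labels = self._fixed_diff_matrix()
        perm = np.random.default_rng(0).permutation(G.n_loci)
        Gp = G.take_loci(perm)
        scans = {p: one_vs_rest_scan(G, labels, p) for p in (1, 2)}
        scans_p = {p: one_vs_rest_scan(Gp, labels, p) for p in (1, 2)}
        a = select_panel(scans, 50, 60).loci.sort_values(["chrom", "pos"])
        b = select_panel(scans_p, 50, 60).loci.sort_values(["chrom", "pos"])
        assert a.reset_index(drop=True).equals(b.reset_index(drop=True))

    def test_high_differentiation_loci_rank_first(self):
        """Loci simulated at c=0.8 against a c=0.02 background dominate the
        top of each scan (>= 90% of the top-S ranked)."""
        from ricepop.simulate import (simulate_accessions,
                                      simulate_ancestral_freqs,
                                      simulate_genotypes)
        S, L_bg = 40, 800
        Q, labels = simulate_accessions((40, 40), seed=1)
        F_hi = simulate_ancestral_freqs(2, S, fst=0.8, seed=1)
        F_lo = simulate_ancestral_freqs(2, L_bg, fst=0.02, seed=2)
        F = np.hstack([F_hi, F_lo])
        G = simulate_genotypes(Q, F, missing_rate=0.0, seed=3)
        scan = one_vs_rest_scan(G, labels + 1, 1)
        # count the high-c loci whose ancestral rows actually diverged (a
        # c=0.8 Beta draw can land both ancestors on the same side)
        true_diff = np.abs(F_hi[0] - F_hi[1])
        S_eff = int((true_diff >= 0.5).sum())
        top = scan.top(S_eff)
        frac = np.mean(top.index < S)
        assert frac >= 0.9


class TestAnnotateGenes:
    def _write_gff(self, tmp_path, rows):
        path = tmp_path / "genes.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for seqid, start, end, gid in rows:
                fh.write(f"{seqid}\tsrc\tgene\t{start}\t{end}\t.\t+\t.\t"
                         f"ID={gid}\n")
        return path

    def _panel_at(self, positions, chrom="1"):
        from ricepop.panel import DiscriminativePanel
        loci = pd.DataFrame({"chrom": chrom, "pos": positions, "best_for": 1,
                             "allele_freq_diff": 1.0, "lod": 50.0})
        return DiscriminativePanel(per_pop={1: loci}, loci=loci,
                                   per_pop_min=1, per_pop_max=10)

    def test_containment_and_inclusive_boundary(self, tmp_path):
        gff = self._write_gff(tmp_path, [("1", 100, 200, "g1")])
        hits, _ = annotate_genes(self._panel_at([150, 200, 201]), gff)
        assert set(hits["pos"]) == {150, 200}  # end coordinate inclusive

    def test_interval_run_genes(self, tmp_path):
        gff = self._write_gff(tmp_path, [("1", 100, 200, "g1"),
                                         ("1", 3000, 5000, "g2"),
                                         ("1", 900_000, 901_000, "g3")])
        panel = self._panel_at([150, 4000, 950_000])
        hits, intervals = annotate_genes(panel, gff, interval_window=100_000)
        # SNPs 150 and 4000 form one run spanning [150, 4000] -> g1, g2
        run1 = intervals.loc[intervals["interval"] == "1:150-4000", "gene_id"]
        assert set(run1) == {"g1", "g2"}
        assert "g3" not in set(run1)

    def test_matches_brute_force_interval_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        genes = [("1", int(s), int(s) + int(rng.integers(50, 500)),
                  f"g{i}") for i, s in
                 enumerate(sorted(rng.choice(100_000, 30, replace=False)))]
        gff = self._write_gff(tmp_path, genes)
        pos = sorted(int(p) for p in rng.choice(100_000, 40, replace=False))
        panel = self._panel_at(pos)
        hits, _ = annotate_genes(panel, gff)
        expected = {(p, gid) for p in pos for (c, s, e, gid) in genes
                    if s <= p <= e}
        got = set(zip(hits["pos"], hits["gene_id"]))
        assert got == expected


class TestCrossValidation:
    def test_f1_identity_and_limits(self, study):
        m = study.cv.metrics
        for _, row in m.iterrows():
            p, r, f1 = row["precision"], row["recall"], row["f1"]
            if p + r > 0:
                assert abs(f1 - 2 * p * r / (p + r)) < 1e-12
            else:
                assert f1 == 0.0

    def test_every_accession_scored_once(self, study):
        conf = study.cv.confusion
        assert int(conf.to_numpy().sum()) == study.Gh.n_accessions

    def test_pure_populations_classified_admixed_hardest(self, study):
        f1 = study.cv.metrics["f1"]
        adm = study.admixed_cluster
        pure = [c for c in f1.index if c != adm]
        assert all(f1[c] >= 0.95 for c in pure)
        assert f1[adm] < min(f1[c] for c in pure)

    def test_perfectly_separable_toy(self):
        vals = np.zeros((24, 10))
        labels = np.repeat([1, 2], 12)
        vals[labels == 2] = 1.0
        rep = crossval_classify(_matrix(vals), labels, folds=4, seed=0)
        assert (rep.metrics["f1"] == 1.0).all()

    def test_fold_reduction_warning(self):
        vals = np.zeros((8, 4))
        vals[4:] = 1.0
        labels = np.repeat([1, 2], 4)
        with pytest.warns(UserWarning, match="reducing"):
            rep = crossval_classify(_matrix(vals), labels, folds=10, seed=1)
        assert rep.folds == 4

    def test_pluggable_estimator(self):
        from sklearn.tree import DecisionTreeClassifier
        vals = np.zeros((20, 5))
        labels = np.repeat([1, 2], 10)
        vals[labels == 2] = 1.0
        rep = crossval_classify(_matrix(vals), labels, folds=5, seed=2,
                                estimator=DecisionTreeClassifier(random_state=0))
        assert (rep.metrics["f1"] == 1.0).all()
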