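"""Population-structure summaries: PCA, neighbor-joining tree, and the
origin-by-subpopulation association test.

PCA operates on the column-centered (unscaled) numeric genotype matrix via
SVD.  The accession tree is classic neighbor joining (Saitou–Nei) on the
1 - identity-by-state distance (mean absolute numeric genotype difference).
Association between geographic origin and inferred subpopulation is a
Pearson chi-square test of independence on the origins x subpopulations
contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PcaResult", "pca", "distance_matrix", "nj_tree",
           "ChiSquareResult", "origin_association_test", "contingency_table",
           "load_origin_table", "read_contingency_csv"]


@dataclass
class PcaResult:
    """Component scores and per-component explained-variance fractions."""

    scores: np.ndarray
    explained_variance: np.ndarray

    def to_frame(self, accession_ids=None) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, columns=cols, index=accession_ids)


def pca(G_complete, m: int = 10) -> PcaResult:
    """PCA of a complete numeric genotype matrix.

    Columns are centered (not scaled); scores are the centered data
    projected on the top-m right singular vectors.  Explained-variance
    fractions are relative to the total variance of the centered matrix.
    ``m`` beyond the matrix rank is truncated with a warning.
    """
    X = np.asarray(G_complete, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA needs a complete matrix; impute first")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if m > rank:
        warnings.warn(f"m={m} exceeds matrix rank {rank}; truncating")
        m = rank
    total = float((s ** 2).sum())
    scores = U[:, :m] * s[:m]
    frac = (s[:m] ** 2) / total if total > 0 else np.zeros(m)
    return PcaResult(scores=scores, explained_variance=frac)


def distance_matrix(G_complete) -> np.ndarray:
    """Pairwise 1 - IBS distance: mean absolute numeric genotype difference.

    Symmetric with zero diagonal; entries in [0, 1] for genotypes on the
    [0, 1] scale.
    """
    X = np.asarray(G_complete, dtype=float)
    if np.isnan(X).any():
        raise ValueError("distance_matrix needs a complete matrix; impute first")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i + 1:] - X[i]).mean(axis=1)
        D[i, i + 1:] = diff
        D[i + 1:, i] = diff
    return D


def nj_tree(D, leaf_names) -> str:
    """Neighbor-joining tree from a distance matrix, as a newick string.

    Classic Saitou–Nei agglomeration: join the pair minimizing
    Q(a, b) = (n-2) d(a, b) - sum_c d(a, c) - sum_c d(b, c); branch lengths
    from the standard formulas, negatives clamped to zero (with a warning).
    Exact on additive distances.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    D = np.asarray(D, dtype=float)
    if D.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    dm = DistanceMatrix(D, ids=[str(x) for x in leaf_names])
    tree = _nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch lengths clamped to 0")
    return str(tree).strip()


@dataclass
class ChiSquareResult:
    """Pearson chi-square test of independence with diagnostics."""

    chi2: float
    dof: int
    p: float
    expected: pd.DataFrame = None

    def __iter__(self):  # allows  chi2, dof, p = origin_association_test(T)
        return iter((self.chi2, self.dof, self.p))


def contingency_table(origins, subpop_labels) -> pd.DataFrame:
    """Cross-tabulate per-accession origins against subpopulation labels."""
    return pd.crosstab(pd.Series(origins, name="origin"),
                       pd.Series(subpop_labels, name="subpopulation"))


def origin_association_test(T: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square on an origins x subpopulations count table.

    dof = (rows - 1)(cols - 1) after dropping any all-zero row or column
    (with a warning); p from the chi-square upper tail.
    """
    T = pd.DataFrame(T)
    if (T.to_numpy() < 0).any():
        raise ValueError("contingency counts must be non-negative")
    zr = T.index[T.sum(axis=1) == 0]
    zc = T.columns[T.sum(axis=0) == 0]
    if len(zr) or len(zc):
        warnings.warn(f"dropping {len(zr)} zero rows and {len(zc)} zero "
                      "columns before testing")
        T = T.drop(index=zr, columns=zc)
    if T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    counts = T.to_numpy()
    if np.allclose(counts, stats.contingency.expected_freq(counts)):
        # perfectly independent table: chi2 exactly 0
        dof = (T.shape[0] - 1) * (T.shape[1] - 1)
        exp = pd.DataFrame(stats.contingency.expected_freq(counts),
                           index=T.index, columns=T.columns)
        return ChiSquareResult(0.0, dof, 1.0, exp)
    chi2, p, dof, exp = stats.chi2_contingency(counts, correction=False)
    expected = pd.DataFrame(exp, index=T.index, columns=T.columns)
    return ChiSquareResult(float(chi2), int(dof), float(p), expected)


def load_origin_table() -> pd.DataFrame:
    """The packaged 300-accession origins x subpopulations table for the
    Thai germplasm panel (10 origins x 5 subpopulations)."""
    with resources.files("ricepop.data").joinpath("thai_rice_origins.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def read_contingency_csv(path) -> pd.DataFrame:
    """Read a labeled contingency table (first column = row labels)."""
    return pd.read_csv(path, index_col=0)
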