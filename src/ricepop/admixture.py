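"""Maximum-likelihood admixture model: ancestry ratios Q and ancestral
allele frequencies F.

Each accession i carries, at locus j, two alleles drawn independently with
coded-1-allele probability p_ij = sum_k q_ik f_kj, where q_i is the
accession's ancestry-ratio vector over K ancestral populations and f_k the
k-th ancestor's allele-frequency vector.  With numeric genotypes
g in {0, 0.5, 1} the log-likelihood is

    l(Q, F) = sum_ij [ 2 g_ij ln p_ij + 2 (1 - g_ij) ln (1 - p_ij) ]

(missing entries contribute zero).  The model is fitted by monotone EM
block updates from a seeded random start, with restarts keeping the best
likelihood.  The number of ancestors is chosen by an elbow rule on the
log-likelihood curve over K, and divergence between inferred ancestors is
summarised by pairwise Hudson-type FST on the F rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["AdmixtureModel", "AdmixtureResults", "fit_admixture",
           "select_K_elbow", "ancestral_fst", "read_q_matrix",
           "write_q_matrix"]

_EPS = 1e-6  # frequency clamp guarding log(0)


@dataclass
class AdmixtureResults:
    """Fitted admixture model.

    Attributes
    ----------
    Q : ndarray (n, K)
        Ancestry ratios; rows sum to 1.
    F : ndarray (K, L)
        Ancestral frequencies of the allele coded 1.0.
    loglik : float
        Binomial admixture log-likelihood at (Q, F).
    converged : bool
        Whether |delta loglik| < tol before max_iter.
    n_iter : int
        EM iterations of the winning restart.
    """

    Q: np.ndarray
    F: np.ndarray
    loglik: float
    K: int
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = None

    def ancestral_fst(self) -> np.ndarray:
        """Pairwise Hudson FST between the inferred ancestors."""
        return ancestral_fst(self.F)

    def summary(self) -> str:
        lines = [
            "Admixture model results",
            "=" * 47,
            f"ancestors (K):       {self.K}",
            f"accessions:          {self.Q.shape[0]}",
            f"loci:                {self.F.shape[1]}",
            f"log-likelihood:      {self.loglik:.3f}",
            f"converged:           {self.converged} ({self.n_iter} iterations)",
            f"mean ancestry ratio: "
            + "  ".join(f"{m:.3f}" for m in self.Q.mean(axis=0)),
        ]
        if self.K >= 2:
            fst = self.ancestral_fst()
            iu = np.triu_indices(self.K, 1)
            lines.append(
                "pairwise ancestral FST: "
                + "  ".join(f"({a+1},{b+1})={fst[a, b]:.3f}"
                            for a, b in zip(*iu)))
        return "\n".join(lines)

    def save(self, q_path, p_path) -> None:
        """Write Q and F as whitespace-delimited tables (.Q/.P convention)."""
        np.savetxt(q_path, self.Q, fmt="%.6f")
        np.savetxt(p_path, self.F.T, fmt="%.6f")


class AdmixtureModel:
    """Admixture model for a numeric genotype matrix.

    Parameters
    ----------
    G : GenotypeMatrix or ndarray
        Accessions x loci numeric genotypes; NaN entries are treated as
        missing and contribute nothing to the likelihood.
    K : int
        Number of ancestral populations, 1 <= K <= n.
    """

    def __init__(self, G, K: int):
        vals = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > vals.shape[0]:
            raise ValueError(f"K={K} exceeds the number of accessions "
                             f"({vals.shape[0]})")
        self.K = int(K)
        miss = np.isnan(vals)
        g = np.where(miss, 0.0, vals)
        # allele counts: a = copies of the coded-1 allele, b = of the other
        self._a = np.where(miss, 0.0, 2.0 * g)
        self._b = np.where(miss, 0.0, 2.0 * (1.0 - g))
        self._valid_per_row = (~miss).sum(axis=1)
        self.n, self.L = vals.shape

    # -- likelihood -------------------------------------------------------

    def loglike(self, Q, F) -> float:
        P = np.clip(Q @ F, _EPS, 1.0 - _EPS)
        return float(np.sum(self._a * np.log(P) + self._b * np.log1p(-P)))

    def _em_step(self, Q, F):
        P = np.clip(Q @ F, _EPS, 1.0 - _EPS)
        WA = self._a / P
        WB = self._b / (1.0 - P)
        # expected allele-origin counts
        numQ = Q * (WA @ F.T + WB @ (1.0 - F).T)
        denom = 2.0 * self._valid_per_row[:, None]
        Qn = numQ / np.maximum(denom, 1.0)
        Qn /= Qn.sum(axis=1, keepdims=True)
        numF = F * (Q.T @ WA)
        denF = numF + (1.0 - F) * (Q.T @ WB)
        with np.errstate(invalid="ignore"):
            Fn = np.where(denF > 0, numF / np.maximum(denF, 1e-300), F)
        return Qn, np.clip(Fn, _EPS, 1.0 - _EPS)

    def _init(self, rng):
        Q = rng.dirichlet(np.ones(self.K), size=self.n)
        F = rng.uniform(0.05, 0.95, size=(self.K, self.L))
        return Q, F

    def fit(self, seed: int = 0, tol: float = 1e-4, max_iter: int = 2000,
            n_restarts: int = 3) -> AdmixtureResults:
        """Fit by EM block updates; keep the best of ``n_restarts`` starts.

        The log-likelihood is non-decreasing across iterations (EM
        guarantee); iteration stops when the improvement drops below
        ``tol`` or at ``max_iter``.
        """
        best = None
        ss = np.random.SeedSequence(seed)
        for child in ss.spawn(max(1, n_restarts)):
            rng = np.random.default_rng(child)
            Q, F = self._init(rng)
            if self.K == 1:
                Q = np.ones((self.n, 1))
            ll = self.loglike(Q, F)
            path = [ll]
            converged = False
            it = 0
            for it in range(1, max_iter + 1):
                Q, F = self._em_step(Q, F)
                ll_new = self.loglike(Q, F)
                path.append(ll_new)
                if abs(ll_new - ll) < tol:
                    converged = True
                    ll = ll_new
                    break
                ll = ll_new
            res = AdmixtureResults(Q=Q, F=F, loglik=ll, K=self.K,
                                   converged=converged, n_iter=it,
                                   loglik_path=np.array(path))
            if best is None or res.loglik > best.loglik:
                best = res
        return best

    def null_loglike(self) -> float:
        """Log-likelihood of the one-parameter null: a single shared allele
        frequency across all loci and accessions."""
        tot_a, tot_b = self._a.sum(), self._b.sum()
        p = np.clip(tot_a / max(tot_a + tot_b, 1.0), _EPS, 1.0 - _EPS)
        return float(tot_a * np.log(p) + tot_b * np.log1p(-p))


def fit_admixture(G, K: int, seed: int = 0, tol: float = 1e-4,
                  max_iter: int = 2000, n_restarts: int = 3) -> AdmixtureResults:
    """Convenience wrapper: ``AdmixtureModel(G, K).fit(...)``."""
    return AdmixtureModel(G, K).fit(seed=seed, tol=tol, max_iter=max_iter,
                                    n_restarts=n_restarts)


def select_K_elbow(G, K_range, seed: int = 0, tol: float = 1e-4,
                   max_iter: int = 200, n_restarts: int = 1,
                   return_curve: bool = False):
    """Choose the number of ancestors by the elbow of the log-likelihood
    curve: the sharpest decay in successive gains.

    With gain(K) = l(K) - l(K-1), the elbow is the K maximizing the ratio
    gain(K) / gain(K+1) — the last K whose improvement dwarfs the next
    one's; ties break toward smaller K.  An extra fit at min(K_range) - 1
    is run when the range starts above 1 so every K except the range
    maximum is a candidate; gain(1) is measured against the single-shared-
    frequency null.  The full per-K log-likelihood curve is available via
    ``return_curve``.
    """
    K_range = sorted(int(k) for k in K_range)
    if len(K_range) < 3:
        raise ValueError("K_range must contain at least 3 values")
    fit_Ks = list(K_range)
    if K_range[0] > 1:
        fit_Ks = [K_range[0] - 1] + fit_Ks
    ll = {}
    model0 = AdmixtureModel(G, 1)
    for K in fit_Ks:
        ll[K] = AdmixtureModel(G, K).fit(seed=seed + K, tol=tol,
                                         max_iter=max_iter,
                                         n_restarts=n_restarts).loglik
    ll[0] = model0.null_loglike()
    gains = {K: ll[K] - ll[K - 1] for K in fit_Ks if K - 1 in ll}
    if any(g < 0 for g in gains.values()):
        warnings.warn("log-likelihood not monotone across K (optimizer "
                      "failure); elbow criterion applied to the curve as-is")
    candidates = [K for K in K_range if K in gains and K + 1 in gains]
    floor = 1e-9
    ratios = {K: max(gains[K], floor) / max(gains[K + 1], floor)
              for K in candidates}
    chosen = min(candidates, key=lambda K: (-ratios[K], K))
    if return_curve:
        curve = {K: ll[K] for K in fit_Ks}
        return chosen, curve
    return chosen


def ancestral_fst(F) -> np.ndarray:
    """Pairwise Hudson-type FST between ancestral frequency rows.

    FST(k, l) = mean_j[(f_kj - f_lj)^2] / mean_j[f_kj(1 - f_lj) +
    f_lj(1 - f_kj)]; a zero denominator (identical fixed rows) gives 0.
    Returns a symmetric K x K matrix with zero diagonal.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("ancestral_fst needs a K x L matrix with K >= 2")
    K = F.shape[0]
    out = np.zeros((K, K))
    for k in range(K):
        for l in range(k + 1, K):
            num = np.mean((F[k] - F[l]) ** 2)
            den = np.mean(F[k] * (1 - F[l]) + F[l] * (1 - F[k]))
            out[k, l] = out[l, k] = num / den if den > 0 else 0.0
    return out


def write_q_matrix(Q, path) -> None:
    np.savetxt(path, np.asarray(Q), fmt="%.6f")


def read_q_matrix(path) -> np.ndarray:
    Q = np.loadtxt(path, ndmin=2)
    return Q
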