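"""Synthetic admixture-model data generator with known truth.

Emulates a nation-wide inbred rice germplasm panel: K ancestral populations
diverged from a common base under the Balding–Nichols model, n accessions
drawn either nearly pure (one dominant ancestor) or admixed between two
ancestors (Dirichlet mixing ratios), genotypes sampled at mostly-selfed
(high-inbreeding) bi-allelic SNPs with missing calls, and replicated
quantitative traits with subpopulation-specific means and high broad-sense
heritability.  Every downstream stage of the pipeline has a parameter-
recovery test against the truth stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SyntheticTruth",
    "simulate_ancestral_freqs",
    "simulate_accessions",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_origins",
    "default_fixture",
    "write_labels_csv",
    "write_traits_csv",
    "write_synthetic_gff3",
    "DEFAULT_POP_SIZES",
    "DEFAULT_ADMIX_SPEC",
    "DEFAULT_TRAIT_MEANS",
    "DEFAULT_SIGMA_G2",
    "DEFAULT_SIGMA_E2",
]

# Default study conditions: five subpopulations sized as in the Thai panel,
# the second one admixed between the ancestors of the first and third.
DEFAULT_POP_SIZES = (54, 45, 67, 92, 42)
DEFAULT_ADMIX_SPEC = {1: (0, 1, 8.0)}  # pop index -> (parent_a, parent_b, Dirichlet conc.)

# Trait means per subpopulation (flowering in days, ordered so the admixed
# group is intermediate between its parents; height in cm; grain length in mm).
DEFAULT_TRAIT_MEANS = {
    "flowering_time": (85.0, 95.0, 105.0, 115.0, 100.0),
    "plant_height": (110.0, 130.0, 150.0, 170.0, 120.0),
    "grain_length": (7.0, 8.0, 9.0, 10.0, 6.5),
}
# Variance components giving broad-sense heritability > 0.9 at r = 4.
DEFAULT_SIGMA_G2 = {"flowering_time": 64.0, "plant_height": 225.0, "grain_length": 0.81}
DEFAULT_SIGMA_E2 = {"flowering_time": 16.0, "plant_height": 36.0, "grain_length": 0.16}


@dataclass
class SyntheticTruth:
    """Generating-model truth for one synthetic panel."""

    trueQ: np.ndarray          # n x K ancestry ratios, rows sum to 1
    trueF: np.ndarray          # K x L ancestral frequencies of the allele coded 1.0
    true_labels: np.ndarray    # subpopulation index per accession (0-based)
    target_fst: np.ndarray     # per-ancestor Balding-Nichols differentiation
    pop_trait_means: dict = field(default_factory=dict)
    sigma_g2: dict = field(default_factory=dict)
    sigma_e2: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not np.allclose(self.trueQ.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("trueQ rows must sum to 1")
        if ((self.trueQ < 0) | (self.trueQ > 1)).any():
            raise ValueError("trueQ entries must lie in [0, 1]")
        if ((self.trueF < 0) | (self.trueF > 1)).any():
            raise ValueError("trueF entries must lie in [0, 1]")
        if len(self.true_labels) != self.trueQ.shape[0]:
            raise ValueError("one label per accession required")


def simulate_ancestral_freqs(K: int, L: int, fst, base_freq_range=(0.1, 0.9),
                             seed: int = 0) -> np.ndarray:
    """Draw K x L ancestral allele frequencies under Balding–Nichols.

    Base frequencies p_j ~ Uniform(base_freq_range); ancestor k's frequency
    f_kj ~ Beta(p_j (1-c_k)/c_k, (1-p_j)(1-c_k)/c_k) with c_k = fst[k].
    The pairwise Hudson FST between two rows with parameter c has
    expectation c (ratio of averages).  Deterministic given seed.
    """
    if K < 1 or L < 1:
        raise ValueError("K and L must be >= 1")
    fst = np.broadcast_to(np.asarray(fst, dtype=float), (K,)).copy()
    if ((fst <= 0) | (fst >= 1)).any():
        raise ValueError("fst values must lie strictly in (0, 1); c=0 gives "
                         "non-finite Beta parameters")
    lo, hi = base_freq_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("base_freq_range must be an interval inside (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=L)
    F = np.empty((K, L))
    for k in range(K):
        scale = (1.0 - fst[k]) / fst[k]
        F[k] = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(F, 0.0, 1.0)


def simulate_accessions(pop_sizes, admix_spec=None, purity: float = 0.97,
                        seed: int = 0):
    """Draw ancestry-ratio rows and subpopulation labels.

    Pure subpopulations get near-degenerate rows: the dominant ancestor's
    weight is 1 - Uniform(0, 1 - purity) (>= purity >= 0.95), the remainder
    split uniformly over the other ancestors.  Each admixed subpopulation
    mixes two parent ancestors with weights ~ Dirichlet(conc, conc).

    Parameters
    ----------
    pop_sizes : sequence of int
        Accession count per subpopulation, in label order.
    admix_spec : dict, optional
        Maps a subpopulation index to ``(parent_a, parent_b, concentration)``
        where the parents are ancestor indices.  Ancestor indices are
        assigned to the pure subpopulations in order, so with five
        subpopulations and one admixed there are K = 4 ancestors.

    Returns
    -------
    (trueQ, true_labels)
    """
    admix_spec = dict(admix_spec or {})
    pop_sizes = list(pop_sizes)
    if purity < 0.95:
        raise ValueError("pure rows require dominant ancestor weight >= 0.95")
    n_pops = len(pop_sizes)
    pure_pops = [p for p in range(n_pops) if p not in admix_spec]
    K = len(pure_pops)
    ancestor_of = {p: k for k, p in enumerate(pure_pops)}
    for p, (a, b, conc) in admix_spec.items():
        if not (0 <= a < K and 0 <= b < K) or a == b:
            raise ValueError(f"admix_spec for subpopulation {p} references "
                             f"unknown or duplicate ancestor indices ({a}, {b})")
        if conc <= 0:
            raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for p, size in enumerate(pop_sizes):
        for _ in range(size):
            q = np.zeros(K)
            if p in admix_spec:
                a, b, conc = admix_spec[p]
                w = rng.dirichlet([conc, conc])
                q[a], q[b] = w
            else:
                dom = ancestor_of[p]
                w_dom = 1.0 - rng.uniform(0.0, 1.0 - purity)
                q[dom] = w_dom
                if K > 1:
                    others = [k for k in range(K) if k != dom]
                    q[others] = (1.0 - w_dom) * rng.dirichlet(np.ones(K - 1))
            rows.append(q)
            labels.append(p)
    return np.array(rows), np.array(labels, dtype=int)


def simulate_genotypes(trueQ, trueF, missing_rate: float = 0.05,
                       inbreeding: float = 0.99, seed: int = 0) -> GenotypeMatrix:
    """Sample numeric genotypes from the admixture model.

    Each accession i at locus j carries the coded-1 allele with probability
    p_ij = sum_k q_ik f_kj.  With probability ``inbreeding`` the accession is
    autozygous at the locus (dose = 2 * Bernoulli(p_ij), as for a selfing
    rice line); otherwise the dose ~ Binomial(2, p_ij).  Numeric genotype =
    dose / 2; entries are masked missing independently at ``missing_rate``.
    ``inbreeding=0`` recovers the plain Hardy–Weinberg binomial draw.
    """
    trueQ = np.asarray(trueQ, dtype=float)
    trueF = np.asarray(trueF, dtype=float)
    if trueQ.ndim != 2 or trueF.ndim != 2 or trueQ.shape[1] != trueF.shape[0]:
        raise ValueError(f"shape mismatch: Q is {trueQ.shape}, F is {trueF.shape}")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if not 0.0 <= inbreeding <= 1.0:
        raise ValueError("inbreeding must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    P = trueQ @ trueF
    n, L = P.shape
    auto = rng.random((n, L)) < inbreeding
    dose = rng.binomial(2, P)
    dose[auto] = 2 * rng.binomial(1, P[auto])
    vals = dose / 2.0
    if missing_rate > 0:
        vals[rng.random((n, L)) < missing_rate] = np.nan
    return GenotypeMatrix(vals, loci=_synthetic_loci(L, rng))


def _synthetic_loci(L: int, rng, n_chrom: int = 12,
                    chrom_len: int = 30_000_000) -> pd.DataFrame:
    """Genome-like locus coordinates: L SNPs spread over ``n_chrom``
    chromosomes at sorted unique random positions, random REF/ALT bases."""
    chroms = np.sort(rng.integers(1, n_chrom + 1, size=L))
    pos = np.empty(L, dtype=np.int64)
    for c in range(1, n_chrom + 1):
        m = chroms == c
        k = int(m.sum())
        p = rng.choice(chrom_len, size=k, replace=False) + 1
        pos[m] = np.sort(p)
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=L)
    alt = (ref + rng.integers(1, 4, size=L)) % 4
    return pd.DataFrame({"chrom": chroms.astype(str), "pos": pos,
                         "ref": bases[ref], "alt": bases[alt]})


def simulate_phenotypes(true_labels, pop_trait_means, sigma_g2, sigma_e2,
                        r: int = 4, seed: int = 0,
                        accession_ids=None) -> pd.DataFrame:
    """Replicated trait records under a genetic + residual variance model.

    Accession genetic value ~ Normal(subpopulation mean, sigma_g2[trait]);
    each of r replicate records adds Normal(0, sigma_e2[trait]) noise, so
    the expected broad-sense heritability of accession means is
    sigma_g2 / (sigma_g2 + sigma_e2 / r).

    Returns a long-format DataFrame with columns
    (accession_id, replicate, trait, value).
    """
    true_labels = np.asarray(true_labels, dtype=int)
    if r < 1:
        raise ValueError("replicate count r must be >= 1")
    n = len(true_labels)
    if accession_ids is None:
        accession_ids = [f"ACC{i:04d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    frames = []
    for trait, means in pop_trait_means.items():
        sg2, se2 = float(sigma_g2[trait]), float(sigma_e2[trait])
        if sg2 < 0 or se2 < 0:
            raise ValueError(f"negative variance component for trait {trait!r}")
        mu = np.asarray(means, dtype=float)[true_labels]
        genetic = mu + rng.normal(0.0, np.sqrt(sg2), size=n)
        obs = genetic[:, None] + rng.normal(0.0, np.sqrt(se2), size=(n, r))
        frames.append(pd.DataFrame({
            "accession_id": np.repeat(accession_ids, r),
            "replicate": np.tile(np.arange(1, r + 1), n),
            "trait": trait,
            "value": obs.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_origins(true_labels, fidelity: float = 0.8, seed: int = 0,
                     region_names=None) -> list[str]:
    """Assign a geographic origin per accession, correlated with its
    subpopulation: the home region with probability ``fidelity``, else a
    uniformly random region.  Supplies the origin column used by the
    origin-by-subpopulation association test on synthetic runs."""
    true_labels = np.asarray(true_labels, dtype=int)
    n_pops = int(true_labels.max()) + 1
    if region_names is None:
        region_names = [f"Region{p + 1}" for p in range(n_pops)]
    rng = np.random.default_rng(seed)
    out = []
    for lab in true_labels:
        if rng.random() < fidelity:
            out.append(region_names[lab % len(region_names)])
        else:
            out.append(region_names[rng.integers(len(region_names))])
    return out


def default_fixture(seed: int = 0, n_loci: int = 5000, fst=0.3,
                    missing_rate: float = 0.05, inbreeding: float = 0.99,
                    r: int = 4):
    """The default synthetic panel: K=4 ancestors, five subpopulations sized
    (54, 45, 67, 92, 42) with the 45-accession group admixed between
    ancestors A and B, plus three replicated traits.

    Returns (GenotypeMatrix, PhenotypeTable DataFrame, SyntheticTruth).
    """
    ss = np.random.SeedSequence(seed)
    s_f, s_q, s_g, s_p = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    trueQ, labels = simulate_accessions(DEFAULT_POP_SIZES, DEFAULT_ADMIX_SPEC,
                                        seed=s_q)
    K = trueQ.shape[1]
    trueF = simulate_ancestral_freqs(K, n_loci, fst, seed=s_f)
    G = simulate_genotypes(trueQ, trueF, missing_rate=missing_rate,
                           inbreeding=inbreeding, seed=s_g)
    pheno = simulate_phenotypes(labels, DEFAULT_TRAIT_MEANS, DEFAULT_SIGMA_G2,
                                DEFAULT_SIGMA_E2, r=r, seed=s_p,
                                accession_ids=G.accession_ids)
    truth = SyntheticTruth(trueQ=trueQ, trueF=trueF, true_labels=labels,
                           target_fst=np.broadcast_to(np.asarray(fst, float), (K,)).copy(),
                           pop_trait_means=dict(DEFAULT_TRAIT_MEANS),
                           sigma_g2=dict(DEFAULT_SIGMA_G2),
                           sigma_e2=dict(DEFAULT_SIGMA_E2), seed=seed)
    return G, pheno, truth


# -- text writers ----------------------------------------------------------

def write_labels_csv(accession_ids, labels, path, extra=None) -> None:
    df = pd.DataFrame({"accession_id": accession_ids,
                       "subpopulation": np.asarray(labels) + 1})
    if extra:
        for k, v in extra.items():
            df[k] = v
    df.to_csv(path, index=False)


def write_traits_csv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def write_synthetic_gff3(loci: pd.DataFrame, path, gene_span: int = 3000,
                         every: int = 5, seed: int = 0) -> pd.DataFrame:
    """Write a minimal synthetic GFF3 with gene intervals covering roughly
    every ``every``-th locus, for annotation tests.  Returns the gene table."""
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for chrom in loci["chrom"].unique():
        pos = np.sort(loci.loc[loci["chrom"] == chrom, "pos"].to_numpy())
        for p in pos[::every]:
            gid += 1
            start = max(1, int(p) - int(rng.integers(0, gene_span // 2 + 1)))
            rows.append({"seqid": str(chrom), "start": start,
                         "end": start + gene_span,
                         "gene_id": f"SYNGENE{gid:05d}"})
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            fh.write(f"{row['seqid']}\tricepop\tgene\t{row['start']}\t"
                     f"{row['end']}\t.\t+\t.\tID={row['gene_id']};"
                     f"Name={row['gene_id']}\n")
    return pd.DataFrame(rows)
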