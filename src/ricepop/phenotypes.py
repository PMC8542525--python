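"""Replicated-trait analysis: broad-sense heritability and domination
graphs over subpopulations.

Broad-sense heritability of accession means with r replicates is

    h2_B = sigma_G^2 / (sigma_G^2 + sigma_e^2 / r)

with variance components estimated by one-way random-effects ANOVA
(method of moments): sigma_e^2 = MS_within, sigma_G^2 = (MS_between -
MS_within) / r, floored at zero.

A domination graph draws a directed edge from subpopulation A to B for a
trait when A's per-accession trait values are significantly stochastically
greater than B's by a one-sided Mann-Whitney test at level alpha (0.001 by
default, per-pair, uncorrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["broad_sense_heritability", "mann_whitney_one_sided",
           "DominationGraph", "domination_graph", "read_traits_csv"]


def read_traits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"accession_id", "replicate", "trait", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"traits CSV must have columns {sorted(required)}")
    return df


def broad_sense_heritability(P: pd.DataFrame, trait: str) -> float:
    """Broad-sense heritability of accession means for one trait.

    One-way random-effects ANOVA over accessions: the within-accession mean
    square estimates the residual variance, and (MS_between - MS_within)/r
    the genetic variance (floored at 0).  Requires replicated records
    (r >= 2); an unbalanced design uses the mean replicate count with a
    warning.
    """
    sub = P.loc[P["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    groups = sub.groupby("accession_id")["value"]
    counts = groups.count()
    n = len(counts)
    if n < 2:
        raise ValueError("need at least 2 accessions")
    if counts.min() < 2:
        raise ValueError("r=1: residual variance is inestimable; need "
                         "replicated records")
    if counts.nunique() > 1:
        warnings.warn("unbalanced replicates; using the mean replicate count")
    r = float(counts.mean())
    grand = sub["value"].mean()
    means = groups.mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((sub["value"] - means.loc[sub["accession_id"]].to_numpy()) ** 2).sum())
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (counts.sum() - n)
    sigma_e2 = ms_within
    sigma_g2 = max((ms_between - ms_within) / r, 0.0)
    denom = sigma_g2 + sigma_e2 / r
    return sigma_g2 / denom if denom > 0 else 0.0


def mann_whitney_one_sided(x, y):
    """One-sided Mann-Whitney: is x stochastically greater than y?

    U = #{(i, j): x_i > y_j} + half the ties.  The p-value is exact by
    enumeration when min(n_x, n_y) <= 8 and there are no ties, else a
    tie-corrected normal approximation with continuity correction.

    Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DominationGraph:
    """Directed higher-to-lower trait relationships between subpopulations.

    ``edges`` rows: (trait, from_pop, to_pop, U, p); at most one direction
    per pair (both one-sided tests cannot pass at alpha < 0.5).
    """

    trait: str
    nodes: list
    edges: pd.DataFrame
    alpha: float
    excluded: list = field(default_factory=list)

    def to_dot(self) -> str:
        lines = [f'digraph "{self.trait}" {{']
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for row in self.edges.itertuples(index=False):
            lines.append(f'  "{row.from_pop}" -> "{row.to_pop}" '
                         f'[label="p={row.p:.2e}"];')
        lines.append("}")
        return "\n".join(lines)


def domination_graph(P: pd.DataFrame, labels: dict | pd.Series, trait: str,
                     alpha: float = 0.001) -> DominationGraph:
    """Infer the domination graph for one trait.

    Per-accession values are replicate means; for each unordered pair of
    subpopulations both one-sided Mann-Whitney tests run, and A -> B is
    added iff p(A > B) <= alpha.  Subpopulations with fewer than 2
    accessions are excluded with a warning.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5) for antisymmetry")
    labels = pd.Series(dict(labels) if isinstance(labels, dict) else labels)
    sub = P.loc[P["trait"] == trait]
    acc_means = sub.groupby("accession_id")["value"].mean()
    lab = labels.reindex(acc_means.index)
    groups = {}
    excluded = []
    for g, block in acc_means.groupby(lab):
        if len(block) < 2:
            excluded.append(g)
        else:
            groups[g] = block.to_numpy()
    if excluded:
        warnings.warn(f"excluding subpopulations with <2 accessions: {excluded}")
    if len(groups) < 2:
        raise ValueError("need at least 2 subpopulations with >= 2 accessions")
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            u_ab, p_ab = mann_whitney_one_sided(groups[a], groups[b])
            u_ba, p_ba = mann_whitney_one_sided(groups[b], groups[a])
            if p_ab <= alpha:
                rows.append((trait, a, b, u_ab, p_ab))
            elif p_ba <= alpha:
                rows.append((trait, b, a, u_ba, p_ba))
    edges = pd.DataFrame(rows, columns=["trait", "from_pop", "to_pop", "U", "p"])
    return DominationGraph(trait=trait, nodes=names, edges=edges, alpha=alpha,
                           excluded=excluded)
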