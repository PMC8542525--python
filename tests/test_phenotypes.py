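"""Heritability estimation, Mann-Whitney tests and domination graphs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ricepop.phenotypes import (broad_sense_heritability, domination_graph,
                                mann_whitney_one_sided)
from ricepop.simulate import simulate_phenotypes


def _table(values_by_acc, trait="t"):
    rows = []
    for acc, vals in values_by_acc.items():
        for rep, v in enumerate(vals, start=1):
            rows.append({"accession_id": acc, "replicate": rep,
                         "trait": trait, "value": float(v)})
    return pd.DataFrame(rows)


class TestHeritability:
    def test_zero_within_variance_gives_one(self):
        P = _table({"a": [1, 1], "b": [5, 5], "c": [9, 9]})
        assert broad_sense_heritability(P, "t") == pytest.approx(1.0)

    def test_pure_noise_floored_at_zero(self):
        rng = np.random.default_rng(0)
        P = _table({f"a{i}": rng.normal(0, 1, 4) for i in range(50)})
        assert broad_sense_heritability(P, "t") < 0.2

    def test_recovers_generating_value(self):
        labels = np.zeros(500, dtype=int)
        P = simulate_phenotypes(labels, {"t": (50.0,)}, {"t": 9.0}, {"t": 4.0},
                                r=4, seed=2)
        assert abs(broad_sense_heritability(P, "t") - 0.9) < 0.05

    def test_estimator_bias_small_across_h2_levels(self):
        """Method-of-moments bias below 0.02 at n=500 for h2 in
        {0.5, 0.8, 0.95} (20 seeds each; sigma_G^2=1, r=4)."""
        labels = np.zeros(500, dtype=int)
        for h2 in (0.5, 0.8, 0.95):
            se2 = 4 * (1 - h2) / h2  # so that 1/(1 + se2/4) = h2
            ests = [broad_sense_heritability(
                simulate_phenotypes(labels, {"t": (0.0,)}, {"t": 1.0},
                                    {"t": se2}, r=4, seed=s), "t")
                for s in range(20)]
            assert abs(np.mean(ests) - h2) < 0.02

    def test_single_replicate_rejected(self):
        P = _table({"a": [1], "b": [2]})
        with pytest.raises(ValueError, match="r=1"):
            broad_sense_heritability(P, "t")

    def test_unbalanced_warns(self):
        P = _table({"a": [1, 2, 3], "b": [4, 5]})
        with pytest.warns(UserWarning, match="unbalanced"):
            broad_sense_heritability(P, "t")


def _enumeration_p(x, y):
    """Exact one-sided p by full enumeration over label arrangements."""
    x, y = list(x), list(y)
    pooled = x + y
    n_x = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj) \
            + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        if u >= u_obs:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        # x=(5,6), y=(1,2): U=4; enumeration over C(4,2)=6 arrangements -> 1/6
        U, p = mann_whitney_one_sided([5, 6], [1, 2])
        assert U == 4
        assert p == pytest.approx(1 / 6)
        assert p == pytest.approx(_enumeration_p([5, 6], [1, 2]))

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(0, 1, rng.integers(3, 7))
            y = rng.normal(0.5, 1, rng.integers(3, 7))
            U, p = mann_whitney_one_sided(x, y)
            assert p == pytest.approx(_enumeration_p(x, y), abs=1e-12)

    def test_identical_samples_no_evidence(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney_one_sided(x, x)
        assert p >= 0.5

    def test_swap_symmetry_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 1, 5)
        U_xy, _ = mann_whitney_one_sided(x, y)
        U_yx, _ = mann_whitney_one_sided(y, x)
        assert U_xy + U_yx == pytest.approx(len(x) * len(y))

    def test_exact_and_normal_paths_agree_at_boundary(self):
        """At n_x = n_y = 8 the exact and tie-corrected normal p-values
        agree within 0.01 on 100 random samples."""
        from scipy import stats
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.3, 1, 8)
            _, p_exact = mann_whitney_one_sided(x, y)  # takes the exact path
            p_norm = stats.mannwhitneyu(x, y, alternative="greater",
                                        method="asymptotic").pvalue
            assert abs(p_exact - p_norm) <= 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])


class TestDominationGraph:
    def _pheno(self, means, n=30, sd=1.0, r=3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        labels = {}
        for g, mu in enumerate(means):
            for i in range(n):
                acc = f"P{g}_{i}"
                labels[acc] = f"POP{g + 1}"
                for rep in range(1, r + 1):
                    rows.append({"accession_id": acc, "replicate": rep,
                                 "trait": "t",
                                 "value": rng.normal(mu, sd)})
        return pd.DataFrame(rows), labels

    def test_ordered_groups_give_complete_transitive_tournament(self):
        P, labels = self._pheno([0, 10, 20, 30, 40])
        dg = domination_graph(P, labels, "t", alpha=0.001)
        assert len(dg.edges) == 10
        expected = {(f"POP{j + 1}", f"POP{i + 1}")
                    for i in range(5) for j in range(i + 1, 5)}
        got = {(r.from_pop, r.to_pop) for r in dg.edges.itertuples(index=False)}
        assert got == expected

    def test_null_groups_rarely_connected(self):
        P, labels = self._pheno([0, 0, 0, 0, 0], seed=1)
        dg = domination_graph(P, labels, "t", alpha=0.001)
        assert len(dg.edges) == 0

    def test_two_equal_mean_groups_no_edge(self):
        P, labels = self._pheno([5, 5], seed=2)
        dg = domination_graph(P, labels, "t", alpha=0.001)
        assert len(dg.edges) == 0

    def test_antisymmetric_at_most_one_direction(self):
        P, labels = self._pheno([0, 3, 6], seed=3)
        dg = domination_graph(P, labels, "t", alpha=0.01)
        pairs = {frozenset((r.from_pop, r.to_pop))
                 for r in dg.edges.itertuples(index=False)}
        assert len(pairs) == len(dg.edges)
        assert not any(r.from_pop == r.to_pop
                       for r in dg.edges.itertuples(index=False))

    def test_small_group_excluded_with_warning(self):
        P, labels = self._pheno([0, 10], n=30)
        solo = _table_row = {"accession_id": "solo", "replicate": 1,
                             "trait": "t", "value": 99.0}
        P = pd.concat([P, pd.DataFrame([solo])], ignore_index=True)
        labels["solo"] = "POP9"
        with pytest.warns(UserWarning, match="excluding"):
            dg = domination_graph(P, labels, "t", alpha=0.001)
        assert "POP9" not in dg.nodes

    def test_flowering_order_on_study_fixture(self, study):
        """Flowering-time domination reproduces the generating order with
        the admixed group intermediate between its parent populations."""
        labels = {acc: f"POP{p + 1}" for acc, p in
                  zip(study.G.accession_ids, study.truth.true_labels)}
        dg = domination_graph(study.pheno, labels, "flowering_time",
                              alpha=0.001)
        got = {(r.from_pop, r.to_pop) for r in dg.edges.itertuples(index=False)}
        # generating means: POP1 85 < POP2 95 < POP3 105 < POP4 115
        for hi, lo in [("POP2", "POP1"), ("POP3", "POP2"), ("POP4", "POP3"),
                       ("POP3", "POP1"), ("POP4", "POP1"), ("POP4", "POP2")]:
            assert (hi, lo) in got
            assert (lo, hi) not in got

    def test_alpha_validation(self):
        P, labels = self._pheno([0, 1])
        with pytest.raises(ValueError, match="alpha"):
            domination_graph(P, labels, "t", alpha=0.7)
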