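"""Survival stratification, Mantel-Cox log-rank, patient clustering."""

import numpy as np
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank
from sklearn.metrics import adjusted_rand_score

from discosig import (
    ExpressionCohort,
    MatrixTable,
    SurvivalRecord,
    UndefinedStatisticError,
    ValidationError,
    cluster_patients,
    geneset_score,
    logrank_test,
    q4_vs_q1_survival,
    quartile_stratify,
)
from oracles import naive_logrank_chi2


def make_cohort(values, subgroups=None, survival=None):
    n_genes, n_pat = values.shape
    patients = [f"p{i:03d}" for i in range(n_pat)]
    return ExpressionCohort(
        expr=MatrixTable([f"g{i}" for i in range(n_genes)], patients, values),
        subgroup={p: (subgroups[i] if subgroups else "X") for i, p in enumerate(patients)},
        survival=survival and dict(zip(patients, survival)),
    )


class TestGenesetScore:
    def test_single_gene_set_equals_row(self):
        c = make_cohort(np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]]))
        s = geneset_score(c, ["g0"])
        assert list(s.values()) == [1.0, 2.0, 3.0]

    def test_mean_of_two_genes(self):
        c = make_cohort(np.array([[4.0], [6.0]]))
        assert geneset_score(c, ["g0", "g1"])["p000"] == 5.0

    def test_gene_order_irrelevant_and_missing_skipped(self):
        c = make_cohort(np.array([[4.0], [6.0]]))
        assert geneset_score(c, ["g1", "g0", "ghost"]) == geneset_score(c, ["g0", "g1"])

    def test_all_absent_rejected(self):
        c = make_cohort(np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            geneset_score(c, ["ghost"])


class TestQuartiles:
    def test_eight_patients(self):
        score = {f"p{i}": float(i) for i in range(1, 9)}
        q = quartile_stratify(score)
        assert [q[f"p{i}"] for i in range(1, 9)] == [
            "Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"
        ]

    def test_n10_split_documented(self):
        # array_split convention: extras go to the lowest quartiles
        q = quartile_stratify({f"p{i:02d}": float(i) for i in range(10)})
        sizes = [sum(v == f"Q{k}" for v in q.values()) for k in (1, 2, 3, 4)]
        assert sizes == [3, 3, 2, 2]

    def test_sizes_differ_by_at_most_one(self, rng):
        for n in range(8, 40):
            q = quartile_stratify({f"p{i:02d}": float(rng.normal()) for i in range(n)})
            sizes = [sum(v == f"Q{k}" for v in q.values()) for k in (1, 2, 3, 4)]
            assert sum(sizes) == n and max(sizes) - min(sizes) <= 1

    def test_all_tied_scores_assigned_by_id(self):
        q = quartile_stratify({f"p{i}": 1.0 for i in range(8)})
        assert q["p0"] == "Q1" and q["p7"] == "Q4"

    def test_partition_orders_by_score(self, rng):
        score = {f"p{i:02d}": float(rng.normal()) for i in range(17)}
        q = quartile_stratify(score)
        q1_max = max(score[p] for p in q if q[p] == "Q1")
        q4_min = min(score[p] for p in q if q[p] == "Q4")
        assert q1_max <= q4_min

    def test_below_eight_rejected(self):
        with pytest.raises(ValidationError):
            quartile_stratify({f"p{i}": float(i) for i in range(7)})


class TestLogrank:
    def test_symmetric_groups_chi2_zero(self):
        a = [(5.0, 1), (9.0, 0)]
        chi2, p = logrank_test(a, list(a))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        chi2, p = logrank_test([(1, 1), (2, 1)], [(3, 1), (4, 1)])
        assert chi2 == pytest.approx(2.882, abs=0.01)
        assert 0 < p < 1

    def test_no_events_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            logrank_test([(1.0, 0)], [(2.0, 0)])

    def test_matches_brute_force_tables(self, rng):
        """Exact agreement with an explicit per-event-time 2x2 table
        oracle on 500 random small datasets with ties and censoring."""
        for _ in range(500):
            na, nb = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            a = [(float(rng.integers(1, 8)), int(rng.random() < 0.7)) for _ in range(na)]
            b = [(float(rng.integers(1, 8)), int(rng.random() < 0.7)) for _ in range(nb)]
            if sum(e for _, e in a + b) == 0:
                continue
            try:
                chi2, _ = logrank_test(a, b)
            except UndefinedStatisticError:
                continue
            assert chi2 == pytest.approx(naive_logrank_chi2(a, b), abs=1e-12)

    def test_matches_lifelines(self, rng):
        """Independent cross-check against the survival-analysis
        library's Mantel-Cox implementation."""
        for _ in range(50):
            a = [(float(rng.exponential(10)) + 0.1, int(rng.random() < 0.8)) for _ in range(15)]
            b = [(float(rng.exponential(5)) + 0.1, int(rng.random() < 0.8)) for _ in range(15)]
            chi2, p = logrank_test(a, b)
            res = lifelines_logrank(
                [t for t, _ in a], [t for t, _ in b],
                event_observed_A=[e for _, e in a], event_observed_B=[e for _, e in b],
            )
            assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
            assert p == pytest.approx(res.p_value, rel=1e-9)


class TestQ4VsQ1:
    def test_strong_effect_detected(self, rng):
        n = 40
        values = rng.normal(0, 1, size=(2, n))
        score_rank = np.argsort(np.argsort(values.mean(axis=0)))
        # survival strongly tied to the gene-set score: high score dies early
        surv = [
            SurvivalRecord(os_time=1000.0 - 20.0 * r + rng.normal(0, 5), os_event=1)
            for r in score_rank
        ]
        c = make_cohort(values, survival=surv)
        strat = q4_vs_q1_survival(c, ["g0", "g1"])
        assert strat.logrank_p < 0.01
        assert strat.n_q1 == strat.n_q4 == 10

    def test_requires_survival(self):
        c = make_cohort(np.zeros((1, 10)))
        with pytest.raises(ValidationError, match="survival"):
            q4_vs_q1_survival(c, ["g0"])


class TestClustering:
    def separated_cohort(self, rng, n_per=15, sep=10.0):
        a = rng.normal(0, 1, size=(5, n_per))
        b = rng.normal(sep, 1, size=(5, n_per))
        values = np.concatenate([a, b], axis=1)
        labels = ["A"] * n_per + ["B"] * n_per
        return make_cohort(values, subgroups=labels), labels

    def test_separated_clouds_recovered_exactly(self, rng):
        cohort, truth = self.separated_cohort(rng)
        res = cluster_patients(cohort, [f"g{i}" for i in range(5)], k=2)
        labels = [res.labels_at_k[2][p] for p in cohort.patients]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        cohort, _ = self.separated_cohort(rng, n_per=5)
        res = cluster_patients(cohort, [f"g{i}" for i in range(5)], k=10)
        assert len(set(res.labels_at_k[10].values())) == 10

    def test_merge_tree_has_n_minus_1_rows(self, rng):
        cohort, _ = self.separated_cohort(rng, n_per=6)
        res = cluster_patients(cohort, [f"g{i}" for i in range(5)], k=2)
        assert res.linkage_tree.shape == (11, 4)

    def test_patient_order_invariance_up_to_relabel(self, rng):
        cohort, truth = self.separated_cohort(rng)
        perm = list(rng.permutation(len(cohort.patients)))
        shuffled = make_cohort(
            cohort.expr.values[:, perm], subgroups=[truth[i] for i in perm]
        )
        r1 = cluster_patients(cohort, [f"g{i}" for i in range(5)], k=2)
        r2 = cluster_patients(shuffled, [f"g{i}" for i in range(5)], k=2)
        l1 = [r1.labels_at_k[2][p] for p in cohort.patients]
        # shuffled cohort renames its patients positionally, so compare by position
        l2_by_pos = [r2.labels_at_k[2][f"p{j:03d}"] for j in range(len(perm))]
        l2 = [None] * len(perm)
        for new_pos, old_pos in enumerate(perm):
            l2[old_pos] = l2_by_pos[new_pos]
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_constant_genes_dropped_all_constant_rejected(self, rng):
        values = np.ones((3, 12))
        cohort = make_cohort(values)
        with pytest.raises(ValidationError, match="constant"):
            cluster_patients(cohort, ["g0", "g1", "g2"], k=2)
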