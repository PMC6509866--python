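"""Stepwise character selection, CV scoring and the confusion-matrix metrics."""

import math

import numpy as np
import pytest

from grangersift import (
    ConfusionMatrix,
    CvConfig,
    ExpressionMatrix,
    MetricsReport,
    SampleLabels,
    confusion_metrics,
    cv_score,
    rank_candidates,
    stepwise_select,
)


def table_scorer(table):
    """Deterministic scorer over a frozen accuracy table keyed by frozenset."""

    def score(genes):
        return MetricsReport(acc=table[frozenset(genes)], sn=0.0, sp=0.0, mcc=0.0)

    return score


# Fixture 1: exercises a prose removal of an *older* member (A) after C and B
# join, the re-add of A, and a clean while-condition exit.  Hand-simulated.
TABLE_1 = {
    frozenset("A"): 0.70, frozenset("B"): 0.55, frozenset("C"): 0.54, frozenset("D"): 0.40,
    frozenset("AB"): 0.695, frozenset("AC"): 0.71, frozenset("AD"): 0.58,
    frozenset("ABC"): 0.72, frozenset("ACD"): 0.66,
    frozenset("BC"): 0.73, frozenset("ABCD"): 0.69, frozenset("BCD"): 0.66,
}

# Fixture 2: the first add makes the just-added gene an improver, so the two
# removal semantics diverge immediately.  Hand-simulated.
TABLE_2 = {
    frozenset("A"): 0.70, frozenset("B"): 0.55, frozenset("C"): 0.54, frozenset("D"): 0.40,
    frozenset("AB"): 0.695, frozenset("AC"): 0.60, frozenset("AD"): 0.58,
}


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = confusion_metrics(ConfusionMatrix(tp=10, fp=0, tn=10, fn=0))
        assert (rep.acc, rep.sn, rep.sp, rep.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_mixed_case(self):
        rep = confusion_metrics(ConfusionMatrix(tp=3, fp=1, tn=4, fn=2))
        assert rep.acc == pytest.approx(0.7)
        assert rep.sn == pytest.approx(0.6)
        assert rep.sp == pytest.approx(0.8)
        assert rep.mcc == pytest.approx((12 - 2) / math.sqrt(4 * 5 * 5 * 6))

    def test_degenerate_marginal_mcc_zero(self):
        rep = confusion_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert rep.sn == 0.0 and rep.sp == 1.0 and rep.mcc == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=0, fn=0)


class TestCvScore:
    CFG = CvConfig(k_folds=5, n_trees=50, n_repeats=2, seed=7)

    def test_separable_gene_near_perfect(self, two_class_matrix):
        matrix, labels = two_class_matrix
        rep = cv_score(["g000"], matrix, labels, self.CFG)
        assert rep.acc >= 0.98

    def test_permuted_labels_chance_level(self, two_class_matrix, rng):
        matrix, labels = two_class_matrix
        shuffled = SampleLabels(labels.sample_ids, rng.permutation(labels.y))
        rep = cv_score(["g000"], matrix, shuffled, self.CFG)
        assert 0.35 <= rep.acc <= 0.65

    def test_deterministic_under_fixed_seed(self, two_class_matrix):
        matrix, labels = two_class_matrix
        assert cv_score(["g001", "g002"], matrix, labels, self.CFG) == cv_score(
            ["g001", "g002"], matrix, labels, self.CFG
        )

    def test_class_smaller_than_folds_rejected(self, rng):
        samples = tuple(f"s{i}" for i in range(8))
        matrix = ExpressionMatrix(("g",), samples, rng.standard_normal((1, 8)))
        labels = SampleLabels(samples, np.r_[np.ones(3, int), np.zeros(5, int)])
        with pytest.raises(ValueError, match="smaller k"):
            cv_score(["g"], matrix, labels, CvConfig(k_folds=5, n_trees=10, n_repeats=1))

    def test_repeats_reduce_score_variance(self, rng):
        # more CV repetitions -> steadier mean accuracy across scorer seeds
        samples = tuple(f"s{i}" for i in range(40))
        vals = rng.standard_normal((1, 40))
        vals[0, :20] += 1.5
        matrix = ExpressionMatrix(("g",), samples, vals)
        labels = SampleLabels(samples, np.r_[np.ones(20, int), np.zeros(20, int)])
        accs = {
            reps: [
                cv_score(["g"], matrix, labels, CvConfig(n_trees=20, n_repeats=reps, seed=s)).acc
                for s in range(20)
            ]
            for reps in (1, 10)
        }
        assert np.std(accs[10]) < np.std(accs[1])


class TestRankCandidates:
    def test_informative_gene_ranked_first(self, two_class_matrix):
        matrix, labels = two_class_matrix
        ranked = rank_candidates(["g005", "g000"], matrix, labels, TestCvScore.CFG)
        assert ranked[0][0] == "g000"

    def test_equal_scores_break_lexicographically(self):
        scorer = table_scorer({frozenset({"b"}): 0.6, frozenset({"a"}): 0.6})
        ranked = rank_candidates(["b", "a"], scorer=scorer)
        assert [g for g, _ in ranked] == ["a", "b"]

    def test_singleton(self):
        ranked = rank_candidates(["x"], scorer=table_scorer({frozenset("x"): 0.5}))
        assert [g for g, _ in ranked] == ["x"]


class TestStepwiseHandSimulated:
    def test_prose_semantics_fixture1(self):
        """init A; add C; add B; remove A (loo 0.73 > 0.72); re-add A; exit."""
        res = stepwise_select(
            list("ABCD"), epsilon=0.01, scorer=table_scorer(TABLE_1),
            removal_semantics="prose",
        )
        assert res.predictors == ("C", "B", "A")
        assert res.p_acc == pytest.approx(0.72)
        assert not res.hit_iteration_cap
        expected = (
            {"action": "init", "gene": "A", "acc_before": None, "acc_after": 0.70},
            {"action": "add", "gene": "C", "acc_before": 0.70, "acc_after": 0.71},
            {"action": "add", "gene": "B", "acc_before": 0.71, "acc_after": 0.72},
            {"action": "remove", "gene": "A", "acc_before": 0.72, "acc_after": 0.73},
            {"action": "add", "gene": "A", "acc_before": 0.73, "acc_after": 0.72},
        )
        assert res.trace == expected

    def test_pseudocode_semantics_fixture1_empties_panel(self):
        """No improver after the first add: the literal set-builder keeps {}."""
        with pytest.warns(UserWarning, match="emptied"):
            res = stepwise_select(
                list("ABCD"), epsilon=0.01, scorer=table_scorer(TABLE_1),
                removal_semantics="pseudocode",
            )
        assert res.hit_iteration_cap
        assert res.predictors == ("A", "C") and res.p_acc == pytest.approx(0.71)

    def test_prose_semantics_fixture2_cycles_to_cap(self):
        """Removing the just-added improver re-creates the same add forever."""
        with pytest.warns(UserWarning, match="iteration cap"):
            res = stepwise_select(
                list("ABCD"), epsilon=0.01, scorer=table_scorer(TABLE_2),
                removal_semantics="prose", max_iterations=6,
            )
        assert res.hit_iteration_cap
        assert res.predictors == ("A",) and res.p_acc == pytest.approx(0.70)

    def test_pseudocode_semantics_fixture2_keeps_improver(self):
        """Improver B is kept, A returned; while-condition then fails."""
        res = stepwise_select(
            list("ABCD"), epsilon=0.01, scorer=table_scorer(TABLE_2),
            removal_semantics="pseudocode",
        )
        assert not res.hit_iteration_cap
        assert res.predictors == ("B",) and res.p_acc == pytest.approx(0.55)
        assert res.trace[-1] == {
            "action": "remove", "gene": "A", "acc_before": 0.695, "acc_after": 0.55
        }


class TestStepwiseContracts:
    def test_single_candidate(self):
        res = stepwise_select(["A"], epsilon=0.01, scorer=table_scorer({frozenset("A"): 0.8}))
        assert res.predictors == ("A",) and res.p_acc == 0.8

    def test_epsilon_zero_stops_after_first_failed_add(self):
        table = {
            frozenset("A"): 0.9, frozenset("B"): 0.5, frozenset("C"): 0.4,
            frozenset("AB"): 0.85, frozenset("AC"): 0.80,
        }
        res = stepwise_select(list("ABC"), epsilon=0.0, scorer=table_scorer(table))
        assert res.predictors == ("A", "B")
        assert res.p_acc == pytest.approx(0.85)
        assert [t["action"] for t in res.trace] == ["init", "add"]

    def test_trace_reconstructs_panel(self):
        res = stepwise_select(
            list("ABCD"), epsilon=0.01, scorer=table_scorer(TABLE_1),
            removal_semantics="prose",
        )
        panel: list[str] = []
        for entry in res.trace:
            if entry["action"] in ("init", "add"):
                panel.append(entry["gene"])
            else:
                panel.remove(entry["gene"])
        assert tuple(panel) == res.predictors
        assert len(set(res.predictors)) == len(res.predictors)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            stepwise_select(["A"], epsilon=-0.1, scorer=table_scorer({frozenset("A"): 0.5}))
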