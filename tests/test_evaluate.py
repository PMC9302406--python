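"""Fmax, Smin, per-protein F and win counts against exhaustive oracles."""

import math

import pytest

from contactpfp.errors import InputError
from contactpfp.evaluate import (
    THRESHOLD_GRID,
    evaluate,
    fmax,
    per_protein_f,
    smin,
    win_counts,
)
from contactpfp.go_annotation import AnnotationSet
from contactpfp.predict import Prediction


def flat_truth(mapping):
    return AnnotationSet({p: set(ts) for p, ts in mapping.items()}, propagated=True)


def preds(mapping):
    return {p: Prediction(p, dict(s), normalized=True) for p, s in mapping.items()}


def oracle_fmax(predictions, truth):
    """Exhaustive threshold enumeration with flat term sets."""
    best = 0.0
    for t in THRESHOLD_GRID:
        pr_sum, pr_n, rc_sum, n = 0.0, 0, 0.0, 0
        for pid, true_terms in truth.annotations.items():
            if not true_terms:
                continue
            n += 1
            p = predictions.get(pid)
            predicted = {u for u, s in p.scores.items() if s >= t - 1e-12} if p else set()
            tp = len(predicted & true_terms)
            if predicted:
                pr_sum += tp / len(predicted)
                pr_n += 1
            rc_sum += tp / len(true_terms)
        pr = pr_sum / pr_n if pr_n else 0.0
        rc = rc_sum / n if n else 0.0
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def oracle_smin(predictions, truth, ic):
    best = math.inf
    for t in THRESHOLD_GRID:
        ru, mi, n = 0.0, 0.0, 0
        for pid, true_terms in truth.annotations.items():
            n += 1
            p = predictions.get(pid)
            predicted = {u for u, s in p.scores.items() if s >= t - 1e-12} if p else set()
            ru += sum(ic.get(u, 0.0) for u in true_terms - predicted)
            mi += sum(ic.get(u, 0.0) for u in predicted - true_terms)
        best = min(best, math.hypot(ru / n, mi / n))
    return best


THREE_PROTEIN_TRUTH = flat_truth(
    {"p1": {"A", "B"}, "p2": {"B", "C", "D"}, "p3": {"A", "D"}}
)
THREE_PROTEIN_PREDS = preds(
    {
        "p1": {"A": 1.0, "C": 0.6},
        "p2": {"B": 1.0, "C": 0.9, "E": 0.3},
        "p3": {"D": 1.0, "A": 0.45, "B": 0.45},
    }
)
THREE_PROTEIN_IC = {"A": 2.0, "B": 1.0, "C": 1.5, "D": 3.0, "E": 4.0}


class TestFmax:
    def test_perfect_prediction_scores_one(self):
        truth = flat_truth({"p": {f"T{k}" for k in range(8)}})
        p = preds({"p": {f"T{k}": 1.0 for k in range(8)}})
        result = fmax(p, truth)
        assert result.value == pytest.approx(1.0)

    def test_flat_two_term_example(self):
        truth = flat_truth({"p": {"A", "B"}})
        p = preds({"p": {"A": 1.0, "C": 0.6}})
        result = fmax(p, truth)
        # above 0.6 only A is predicted: precision 1, recall 1/2, F = 2/3
        assert result.value == pytest.approx(2 / 3)
        assert result.threshold > 0.6

    def test_empty_predictions_score_zero(self):
        truth = flat_truth({"p1": {"A"}, "p2": {"B"}})
        assert fmax({}, truth).value == 0.0

    def test_matches_exhaustive_enumeration_on_three_protein_fixture(self):
        result = fmax(THREE_PROTEIN_PREDS, THREE_PROTEIN_TRUTH)
        assert result.value == pytest.approx(
            oracle_fmax(THREE_PROTEIN_PREDS, THREE_PROTEIN_TRUTH)
        )

    def test_smallest_maximizing_threshold_reported(self):
        truth = flat_truth({"p": {"A"}})
        p = preds({"p": {"A": 1.0}})
        assert fmax(p, truth).threshold == pytest.approx(0.01)

    def test_protein_with_empty_truth_excluded(self):
        truth = AnnotationSet({"p1": {"A"}, "p2": set()}, propagated=True)
        p = preds({"p1": {"A": 1.0}, "p2": {"B": 1.0}})
        assert fmax(p, truth).value == pytest.approx(1.0)

    def test_recall_nonincreasing_in_threshold(self):
        p = THREE_PROTEIN_PREDS
        truth = THREE_PROTEIN_TRUTH
        recalls = []
        for t in THRESHOLD_GRID:
            rc = 0.0
            for pid, true_terms in truth.annotations.items():
                predicted = {u for u, s in p[pid].scores.items() if s >= t - 1e-12}
                rc += len(predicted & true_terms) / len(true_terms)
            recalls.append(rc / len(truth.annotations))
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))


class TestSmin:
    def test_perfect_prediction_is_zero(self):
        truth = flat_truth({"p": {"A", "B"}})
        p = preds({"p": {"A": 1.0, "B": 1.0}})
        assert smin(p, truth, {"A": 2.0, "B": 3.0}).value == pytest.approx(0.0)

    def test_missed_term_costs_its_information_content(self):
        truth = flat_truth({"p": {"A", "B"}})
        p = preds({"p": {"A": 1.0}})
        result = smin(p, truth, {"A": 2.0, "B": 3.0})
        assert result.value == pytest.approx(3.0)

    def test_overprediction_never_beats_perfection(self):
        truth = flat_truth({"p": {"A"}})
        everything = preds({"p": {"A": 1.0, "B": 1.0, "C": 1.0}})
        perfect = preds({"p": {"A": 1.0}})
        ic = {"A": 1.0, "B": 2.0, "C": 2.0}
        assert smin(everything, truth, ic).value >= smin(perfect, truth, ic).value

    def test_matches_exhaustive_enumeration_on_three_protein_fixture(self):
        result = smin(THREE_PROTEIN_PREDS, THREE_PROTEIN_TRUTH, THREE_PROTEIN_IC)
        assert result.value == pytest.approx(
            oracle_smin(THREE_PROTEIN_PREDS, THREE_PROTEIN_TRUTH, THREE_PROTEIN_IC)
        )

    def test_zero_iff_exact_recovery_possible(self):
        # exact recovery at t > 0.5 -> smin 0; no threshold separates -> smin > 0
        truth = flat_truth({"p1": {"A"}, "p2": {"B"}})
        separable = preds({"p1": {"A": 1.0, "B": 0.3}, "p2": {"B": 1.0}})
        assert smin(separable, truth, {"A": 1.0, "B": 1.0}).value == pytest.approx(0.0)
        inseparable = preds({"p1": {"A": 1.0, "B": 1.0}, "p2": {"B": 1.0}})
        assert smin(inseparable, truth, {"A": 1.0, "B": 1.0}).value > 0.0


class TestPerProteinF:
    def test_exact_match_is_one(self):
        p = Prediction("p", {"A": 1.0, "B": 1.0}, normalized=True)
        assert per_protein_f(p, {"A", "B"}, 0.5) == pytest.approx(1.0)

    def test_empty_prediction_is_zero(self):
        assert per_protein_f(None, {"A"}, 0.5) == 0.0
        p = Prediction("p", {"A": 0.1}, normalized=False)
        assert per_protein_f(p, {"A"}, 0.5) == 0.0

    def test_half_recall_full_precision(self):
        truth = {f"T{k}" for k in range(8)}
        p = Prediction("p", {f"T{k}": 1.0 for k in range(4)}, normalized=True)
        assert per_protein_f(p, truth, 0.5) == pytest.approx(2 / 3)


class TestWinCounts:
    def test_identical_vectors_all_tie(self):
        f = {"p1": 0.5, "p2": 0.7}
        assert win_counts(f, f) == (0, 0, 2)

    def test_split_decision(self):
        a = {"p1": 0.9, "p2": 0.1}
        b = {"p1": 0.5, "p2": 0.5}
        assert win_counts(a, b) == (1, 1, 0)

    def test_strict_domination(self):
        a = {"p1": 0.9, "p2": 0.8, "p3": 0.7}
        b = {"p1": 0.1, "p2": 0.2, "p3": 0.3}
        assert win_counts(a, b) == (3, 0, 0)

    def test_universe_mismatch_lists_difference(self):
        with pytest.raises(InputError, match="p2"):
            win_counts({"p1": 0.5}, {"p1": 0.5, "p2": 0.1})


class TestEvaluateWrapper:
    def test_per_protein_f_at_fmax_threshold(self):
        result = evaluate(THREE_PROTEIN_PREDS, THREE_PROTEIN_TRUTH, ic=THREE_PROTEIN_IC)
        assert set(result.per_protein_f) == {"p1", "p2", "p3"}
        assert result.smin is not None
        for f in result.per_protein_f.values():
            assert 0.0 <= f <= 1.0
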