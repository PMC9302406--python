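"""Protein-centric evaluation: Fmax, Smin, per-protein F, win counts.

Fmax is the maximum, over a score-threshold grid, of the harmonic mean of
(i) precision averaged over proteins with at least one predicted term at
the threshold and (ii) recall averaged over all benchmark proteins.  Smin
is the minimum over the same grid of sqrt(ru^2 + mi^2), where ru is the
mean information content of true-but-unpredicted terms (remaining
uncertainty) and mi of predicted-but-untrue terms (misinformation); lower
is better.  Both truth and predictions are compared as ancestor-closed
term sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import InputError
from .go_annotation import AnnotationSet, Ontology, resolve_namespace
from .predict import Prediction

logger = logging.getLogger(__name__)

#: Score thresholds scanned: 0.01 steps over (0, 1].
THRESHOLD_GRID = tuple(round(k * 0.01, 2) for k in range(1, 101))


@dataclass(frozen=True)
class MetricResult:
    value: float
    threshold: float


@dataclass(frozen=True)
class EvaluationResult:
    fmax: MetricResult
    smin: MetricResult | None
    per_protein_f: dict
    by_namespace: dict


def _closed_scores(pred: Prediction, ont: Ontology | None) -> dict[str, float]:
    """Propagate prediction scores up the ontology (max over descendants),
    dropping roots and unresolvable terms; identity without an ontology."""
    if ont is None:
        return dict(pred.scores)
    out: dict[str, float] = {}
    for t, s in pred.scores.items():
        canon = ont.canonical(t)
        if canon is None:
            continue
        for u in {canon} | ont.ancestors(canon):
            if u in ont.roots:
                continue
            if s > out.get(u, 0.0):
                out[u] = s
    return out


def _namespace_filter(terms, ont: Ontology | None, namespace: str | None):
    if namespace is None or ont is None:
        return set(terms)
    ns = resolve_namespace(namespace)
    return {t for t in terms if ont.namespace(t) == ns}


def _prepare(predictions: dict, truth: AnnotationSet, ont: Ontology | None,
             namespace: str | None, propagate_predictions: bool = True):
    """Pair up, per protein, the (propagated, namespace-filtered) truth set
    with the propagated prediction score map.  Proteins with empty truth in
    the evaluated namespace are excluded with a warning."""
    pairs = []
    for pid in sorted(truth.annotations):
        true_terms = _namespace_filter(truth.annotations[pid], ont, namespace)
        if not true_terms:
            logger.warning("protein %s has no truth terms in scope; excluded", pid)
            continue
        pred = predictions.get(pid)
        scores = _closed_scores(pred, ont) if (pred and propagate_predictions) \
            else dict(pred.scores) if pred else {}
        if namespace is not None and ont is not None:
            keep = _namespace_filter(scores, ont, namespace)
            scores = {t: s for t, s in scores.items() if t in keep}
        pairs.append((pid, true_terms, scores))
    return pairs


def fmax(
    predictions: dict,
    truth: AnnotationSet,
    ont: Ontology | None = None,
    namespace: str | None = None,
    precision_over_all: bool = False,
    propagate_predictions: bool = True,
) -> MetricResult:
    """Maximum protein-averaged F1 over the threshold grid.

    ``predictions`` maps protein id -> Prediction (normalized).  Precision at
    a threshold averages over proteins with >= 1 predicted term unless
    ``precision_over_all`` (strict mode averaging over every protein).
    Reports the smallest maximizing threshold.
    """
    pairs = _prepare(predictions, truth, ont, namespace, propagate_predictions)
    if not pairs:
        return MetricResult(0.0, THRESHOLD_GRID[0])
    best_f, best_t = 0.0, THRESHOLD_GRID[0]
    for t in THRESHOLD_GRID:
        pr_sum, pr_n, rc_sum = 0.0, 0, 0.0
        for _, true_terms, scores in pairs:
            predicted = {u for u, s in scores.items() if s >= t - 1e-12}
            tp = len(predicted & true_terms)
            if predicted:
                pr_sum += tp / len(predicted)
                pr_n += 1
            rc_sum += tp / len(true_terms)
        denom_pr = len(pairs) if precision_over_all else pr_n
        pr = pr_sum / denom_pr if denom_pr else 0.0
        rc = rc_sum / len(pairs)
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if f > best_f + 1e-12:
            best_f, best_t = f, t
    return MetricResult(best_f, best_t)


def smin(
    predictions: dict,
    truth: AnnotationSet,
    ic,
    ont: Ontology | None = None,
    namespace: str | None = None,
    propagate_predictions: bool = True,
) -> MetricResult:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the threshold grid.

    ``ic`` maps term -> information content in bits; terms it lacks fall back
    to its ``guard`` attribute (0 for a plain dict) with a warning.
    Reports the smallest minimizing threshold.
    """
    pairs = _prepare(predictions, truth, ont, namespace, propagate_predictions)
    if not pairs:
        return MetricResult(0.0, THRESHOLD_GRID[0])
    guard = getattr(ic, "guard", 0.0)
    warned: set[str] = set()

    def ic_of(term: str) -> float:
        if term in ic:
            return ic[term]
        if term not in warned:
            warned.add(term)
            logger.warning("no information content for %s; using guard %.3f", term, guard)
        return guard

    best_s, best_t = math.inf, THRESHOLD_GRID[0]
    for t in THRESHOLD_GRID:
        ru_sum, mi_sum = 0.0, 0.0
        for _, true_terms, scores in pairs:
            predicted = {u for u, s in scores.items() if s >= t - 1e-12}
            ru_sum += sum(ic_of(u) for u in true_terms - predicted)
            mi_sum += sum(ic_of(u) for u in predicted - true_terms)
        ru = ru_sum / len(pairs)
        mi = mi_sum / len(pairs)
        s = math.hypot(ru, mi)
        if s < best_s - 1e-12:
            best_s, best_t = s, t
    return MetricResult(best_s, best_t)


def per_protein_f(
    prediction: Prediction | None,
    true_terms: set,
    threshold: float,
    ont: Ontology | None = None,
    namespace: str | None = None,
) -> float:
    """Protein-level F1 of the thresholded predicted set against the truth,
    both ancestor-closed; 0.0 for an empty predicted set."""
    truth_set = _namespace_filter(true_terms, ont, namespace)
    scores = _closed_scores(prediction, ont) if prediction else {}
    if namespace is not None and ont is not None:
        scores = {t: s for t, s in scores.items()
                  if t in _namespace_filter(scores, ont, namespace)}
    predicted = {u for u, s in scores.items() if s >= threshold - 1e-12}
    if not predicted or not truth_set:
        return 0.0
    tp = len(predicted & truth_set)
    pr = tp / len(predicted)
    rc = tp / len(truth_set)
    return 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0


def win_counts(per_protein_f_a: dict, per_protein_f_b: dict) -> tuple[int, int, int]:
    """Head-to-head comparison of per-protein F scores: (wins_a, wins_b, ties).
    Strict inequality counts a win; both inputs must cover the same proteins."""
    if set(per_protein_f_a) != set(per_protein_f_b):
        diff = sorted(set(per_protein_f_a) ^ set(per_protein_f_b))
        raise InputError(f"protein universes differ: {', '.join(diff)}")
    wins_a = wins_b = ties = 0
    for pid, fa in per_protein_f_a.items():
        fb = per_protein_f_b[pid]
        if fa > fb:
            wins_a += 1
        elif fb > fa:
            wins_b += 1
        else:
            ties += 1
    return wins_a, wins_b, ties


def evaluate(
    predictions: dict,
    truth: AnnotationSet,
    ont: Ontology | None = None,
    ic=None,
    namespace: str | None = None,
    precision_over_all: bool = False,
) -> EvaluationResult:
    """Full evaluation: Fmax (with its threshold), Smin when ic is given,
    per-protein F at the Fmax threshold, and a per-namespace breakdown when
    an ontology is available."""
    fm = fmax(predictions, truth, ont, namespace, precision_over_all)
    sm = smin(predictions, truth, ic, ont, namespace) if ic is not None else None
    per_f = {
        pid: per_protein_f(predictions.get(pid), terms, fm.threshold, ont, namespace)
        for pid, terms in truth.annotations.items()
        if _namespace_filter(terms, ont, namespace)
    }
    by_ns = {}
    if ont is not None and namespace is None:
        for ns in ("mf", "bp", "cc"):
            fm_ns = fmax(predictions, truth, ont, ns, precision_over_all)
            sm_ns = smin(predictions, truth, ic, ont, ns) if ic is not None else None
            by_ns[resolve_namespace(ns)] = (fm_ns, sm_ns)
    return EvaluationResult(fm, sm, per_f, by_ns)


def write_metrics_tsv(result: EvaluationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tnamespace\tvalue\tthreshold\n")
        fh.write(f"fmax\tall\t{result.fmax.value:.3f}\t{result.fmax.threshold:.2f}\n")
        if result.smin is not None:
            fh.write(f"smin\tall\t{result.smin.value:.3f}\t{result.smin.threshold:.2f}\n")
        for ns, (fm, sm) in result.by_namespace.items():
            fh.write(f"fmax\t{ns}\t{fm.value:.3f}\t{fm.threshold:.2f}\n")
            if sm is not None:
                fh.write(f"smin\t{ns}\t{sm.value:.3f}\t{sm.threshold:.2f}\n")


def write_per_protein_f_tsv(per_f: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tf_score\n")
        for pid in sorted(per_f):
            fh.write(f"{pid}\t{per_f[pid]:.3f}\n")
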