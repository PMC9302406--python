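"""GO term transfer from selected hits: scoring, normalization, ensembling.

The raw confidence of a GO term is the sum of the graph-similarity scores
of the selected hits annotated with it:

    GOScore(i) = sum over hits k annotated with term i of SimScore(k)

Scores are then divided by the per-protein maximum so the most confident
term gets exactly 1.0.  A uniform mode reproduces the baseline protocol of
assigning 1.0 to every term found among the top hits of a plain database
search.  Predictions from different methods are combined by simple
averaging, with a term absent from a method counting as 0 for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import InputError
from .go_annotation import AnnotationSet, Ontology
from .reference_db import HitList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Prediction:
    """GO term -> confidence score for one query protein."""

    query_id: str
    scores: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.normalized and self.scores:
            vals = list(self.scores.values())
            if any(not (0.0 < v <= 1.0 + 1e-9) for v in vals):
                raise InputError("normalized scores must lie in (0, 1]")
            if abs(max(vals) - 1.0) > 1e-9:
                raise InputError("a normalized nonempty prediction must have max score 1.0")

    def __len__(self) -> int:
        return len(self.scores)

    def terms_at(self, threshold: float) -> set[str]:
        return {t for t, s in self.scores.items() if s >= threshold - 1e-12}


def score_go_terms(
    hits: HitList,
    annotations: AnnotationSet,
    ontology: Ontology | None = None,
    propagate_hits: bool = False,
) -> Prediction:
    """Raw per-term scores: sum of similarity scores of hits carrying the term.

    ``hits`` should already be filtered by the selection policy.  By default a
    hit contributes its direct annotations; with ``propagate_hits`` its
    ancestor-closed set (requires an ontology).
    """
    if propagate_hits and ontology is None:
        raise InputError("propagate_hits requires an ontology")
    scores: dict[str, float] = {}
    missing: list[str] = []
    for ref_id, sim in hits.hits:
        terms = annotations.terms_of(ref_id)
        if not terms:
            missing.append(ref_id)
            continue
        if propagate_hits:
            closed = set(terms)
            for t in terms:
                canon = ontology.canonical(t)
                if canon is not None:
                    closed |= ontology.ancestors(canon)
            terms = closed - ontology.roots
        for t in terms:
            scores[t] = scores.get(t, 0.0) + sim
    for ref_id in missing:
        logger.warning("hit %s has no annotations; contributes nothing", ref_id)
    return Prediction(hits.query_id, scores, normalized=False)


def normalize_prediction(raw: Prediction, per_namespace: Ontology | None = None) -> Prediction:
    """Divide by the highest score so the top term scores exactly 1.0.

    Default is one global maximum per protein across namespaces; passing an
    ontology switches to one maximum per namespace.  Idempotent; an empty
    prediction passes through.
    """
    if not raw.scores:
        return replace(raw, normalized=True)
    if per_namespace is None:
        top = max(raw.scores.values())
        scaled = {t: s / top for t, s in raw.scores.items()}
    else:
        maxima: dict[str, float] = {}
        for t, s in raw.scores.items():
            ns = per_namespace.namespace(t)
            maxima[ns] = max(maxima.get(ns, 0.0), s)
        scaled = {t: s / maxima[per_namespace.namespace(t)] for t, s in raw.scores.items()}
    return Prediction(raw.query_id, scaled, normalized=True)


def uniform_score_from_hits(
    hits: HitList, annotations: AnnotationSet, n: int = 10
) -> Prediction:
    """Baseline scoring: every term found among the top n hits gets 1.0."""
    if n < 1:
        raise InputError("n must be >= 1")
    terms: set[str] = set()
    for ref_id, _ in hits.hits[:n]:
        terms |= annotations.terms_of(ref_id)
    return Prediction(hits.query_id, {t: 1.0 for t in sorted(terms)}, normalized=True)


def ensemble_average(predictions) -> Prediction:
    """Average normalized scores across methods; a term absent from a method
    scores 0 for that method, so the divisor is always the method count."""
    predictions = list(predictions)
    if not predictions:
        raise InputError("ensemble needs at least one prediction")
    query_ids = {p.query_id for p in predictions}
    if len(query_ids) != 1:
        raise InputError(f"ensemble over mismatched queries: {sorted(query_ids)}")
    if any(not p.normalized for p in predictions):
        raise InputError("ensemble inputs must be normalized")
    k = len(predictions)
    totals: dict[str, float] = {}
    for p in predictions:
        for t, s in p.scores.items():
            totals[t] = totals.get(t, 0.0) + s
    averaged = {t: v / k for t, v in totals.items()}
    return Prediction(predictions[0].query_id, averaged,
                      normalized=bool(averaged) and abs(max(averaged.values()) - 1.0) < 1e-9)


# ---------------------------------------------------------------------------
# CAFA-style prediction files: query_id <tab> go_id <tab> score (3 decimals)


def write_prediction_tsv(predictions, path) -> None:
    preds = [predictions] if isinstance(predictions, Prediction) else list(predictions)
    with open(path, "w") as fh:
        for p in preds:
            for t in sorted(p.scores, key=lambda t: (-p.scores[t], t)):
                fh.write(f"{p.query_id}\t{t}\t{p.scores[t]:.3f}\n")


def read_prediction_tsv(path, normalized: bool = True) -> dict[str, Prediction]:
    """Read a CAFA-style prediction file into one Prediction per query."""
    df = pd.read_csv(path, sep="\t", header=None, comment="!",
                     names=["query_id", "go_id", "score"], dtype={0: str, 1: str})
    out: dict[str, Prediction] = {}
    for qid, group in df.groupby("query_id", sort=True):
        scores = dict(zip(group["go_id"], group["score"].astype(float)))
        top = max(scores.values()) if scores else 1.0
        out[str(qid)] = Prediction(str(qid), scores,
                                   normalized=normalized and abs(top - 1.0) < 1e-9)
    return out
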