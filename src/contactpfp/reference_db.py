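"""Reference collection of contact graphs: build, filter, search, select hits.

The database stores one contact graph per reference protein together with
its precomputed graphlet signature, so searching a query is one alignment
per entry.  Hits are the references ranked by graph similarity; three
selection schemes decide which hits contribute GO terms: a raw score
threshold (0.5 in the base protocol), the top N by score (N = 2 with a
12 Å cutoff is the best-performing configuration), or a Z-score relative
to the query's score distribution over the whole database.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .contact_map import ContactGraph
from .errors import ConfigurationError, DegenerateInputError, InputError
from .graph_similarity import align_graphs, count_orbits

logger = logging.getLogger(__name__)

#: Length bounds of the reference collection; sequences shorter than 20 or
#: longer than 2000 residues are excluded (bounds inclusive).
DEFAULT_MIN_LEN = 20
DEFAULT_MAX_LEN = 2000


@dataclass
class ReferenceEntry:
    graph: ContactGraph
    signature: np.ndarray
    mnemonic: str | None = None

    @property
    def length(self) -> int:
        return self.graph.length


@dataclass
class ReferenceDB:
    entries: dict[str, ReferenceEntry]
    cutoff: float
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return sorted(self.entries)


@dataclass(frozen=True)
class HitList:
    """References ranked by graph similarity to one query, best first."""

    query_id: str
    hits: tuple  # of (reference_id, score), descending score

    def __post_init__(self) -> None:
        ids = [r for r, _ in self.hits]
        if len(ids) != len(set(ids)):
            raise InputError(f"duplicate reference ids in hit list for {self.query_id}")
        scores = [s for _, s in self.hits]
        if any(not (0.0 <= s <= 1.0 + 1e-9) for s in scores):
            raise InputError("hit scores must lie in [0, 1]")
        if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
            raise InputError("hit list must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.hits)

    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.hits], dtype=float)


@dataclass(frozen=True)
class SelectionPolicy:
    """How to pick the hits that contribute annotations.

    scheme "score_threshold": keep hits scoring >= parameter (in [0, 1]).
    scheme "top_n": keep the first N hits regardless of score (N >= 1).
    scheme "z_score": keep hits with (s - mean)/std >= parameter (>= 0).
    """

    scheme: str
    parameter: float

    def __post_init__(self) -> None:
        if self.scheme == "score_threshold":
            if not (0.0 <= self.parameter <= 1.0):
                raise ConfigurationError("score_threshold parameter must be in [0, 1]")
        elif self.scheme == "top_n":
            if self.parameter < 1 or int(self.parameter) != self.parameter:
                raise ConfigurationError("top_n parameter must be an integer >= 1")
        elif self.scheme == "z_score":
            if self.parameter < 0:
                raise ConfigurationError("z_score parameter must be >= 0")
        else:
            raise ConfigurationError(f"unknown selection scheme {self.scheme!r}")


#: Best-performing configuration on the full benchmark: top 2 hits at 12 Å.
DEFAULT_POLICY = SelectionPolicy("top_n", 2)


def build_reference_db(
    graphs,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    mnemonics: dict[str, str] | None = None,
) -> ReferenceDB:
    """Assemble a reference database from contact graphs, applying the length
    filter (inclusive bounds) and precomputing graphlet signatures."""
    graphs = list(graphs)
    ids = [g.protein_id for g in graphs]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise InputError(f"duplicate reference ids: {', '.join(dupes)}")
    cutoffs = {g.cutoff for g in graphs}
    if len(cutoffs) > 1:
        raise InputError(f"mixed contact cutoffs in reference graphs: {sorted(cutoffs)}")
    entries: dict[str, ReferenceEntry] = {}
    n_excluded = 0
    for g in graphs:
        if not (min_len <= g.length <= max_len):
            n_excluded += 1
            continue
        mnem = (mnemonics or {}).get(g.protein_id)
        entries[g.protein_id] = ReferenceEntry(g, count_orbits(g), mnem)
    if not entries:
        logger.warning("reference database is empty after length filtering")
    cutoff = cutoffs.pop() if cutoffs else 12.0
    return ReferenceDB(entries, cutoff, min_len, max_len, n_excluded)


def dedup_by_mnemonic(ids) -> set[str]:
    """Keep one UniProt entry name per mnemonic CODE prefix (orthologs across
    species share the CODE in CODE_SPECIES); the lexicographically smallest
    full id of each group is retained.  Ids without an underscore form their
    own group."""
    groups: dict[str, list[str]] = {}
    for name in ids:
        code, sep, _ = name.partition("_")
        if not sep:
            logger.warning("id %r has no mnemonic code separator; kept as its own group", name)
            key = name
        else:
            key = code
        groups.setdefault(key, []).append(name)
    return {min(members) for members in groups.values()}


def search(query: ContactGraph, db: ReferenceDB, gap_score: float = 0.0) -> HitList:
    """Align the query against every database entry and rank by similarity,
    ties broken by ascending reference id."""
    if len(db) == 0:
        raise DegenerateInputError("reference database is empty")
    qsig = count_orbits(query)
    scored = []
    for ref_id in sorted(db.entries):
        entry = db.entries[ref_id]
        res = align_graphs(query, entry.graph, gap_score, sigs1=qsig, sigs2=entry.signature)
        scored.append((ref_id, res.score))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return HitList(query.protein_id, tuple(scored))


def select_hits(
    hits: HitList,
    policy: SelectionPolicy = DEFAULT_POLICY,
    exclusions: set[str] | None = None,
    enforce_score_floor: float | None = None,
) -> HitList:
    """Apply a selection policy after removing excluded reference ids.

    Exclusions implement the benchmark protocol of dropping the query itself
    and any reference flagged as a trivial sequence match (supplied as an id
    list; this module never computes E-values).  ``enforce_score_floor``
    optionally adds a raw-score floor on top of top_n selection.
    """
    excluded = exclusions or set()
    remaining = [(r, s) for r, s in hits.hits if r not in excluded]
    if policy.scheme == "score_threshold":
        kept = [(r, s) for r, s in remaining if s >= policy.parameter - 1e-12]
    elif policy.scheme == "top_n":
        kept = remaining[: int(policy.parameter)]
        if enforce_score_floor is not None:
            kept = [(r, s) for r, s in kept if s >= enforce_score_floor - 1e-12]
    else:  # z_score
        scores = np.array([s for _, s in remaining], dtype=float)
        if len(scores) == 0:
            kept = []
        else:
            sigma = float(scores.std())
            if sigma == 0.0:
                raise ConfigurationError(
                    "z_score selection undefined: all hit scores are equal; "
                    "use score_threshold or top_n instead"
                )
            mu = float(scores.mean())
            kept = [(r, s) for r, s in remaining if (s - mu) / sigma >= policy.parameter - 1e-12]
    return HitList(hits.query_id, tuple(kept))


# ---------------------------------------------------------------------------
# persistence: one JSON archive of edge lists + signature arrays + metadata


def save_db(db: ReferenceDB, path) -> None:
    payload = {
        "format": "contactpfp-db-v1",
        "meta": {
            "cutoff": db.cutoff,
            "min_len": db.min_len,
            "max_len": db.max_len,
            "n_excluded": db.n_excluded,
        },
        "entries": {
            ref_id: {
                "length": e.graph.length,
                "min_separation": e.graph.min_separation,
                "mnemonic": e.mnemonic,
                "edges": sorted(map(list, e.graph.edges)),
                "signature": e.signature.tolist(),
            }
            for ref_id, e in db.entries.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_db(path) -> ReferenceDB:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "contactpfp-db-v1":
        raise InputError(f"{path}: not a contactpfp database archive")
    meta = payload["meta"]
    entries = {}
    for ref_id, rec in payload["entries"].items():
        graph = ContactGraph(
            ref_id,
            rec["length"],
            meta["cutoff"],
            frozenset(tuple(e) for e in rec["edges"]),
            rec["min_separation"],
        )
        entries[ref_id] = ReferenceEntry(
            graph, np.asarray(rec["signature"], dtype=np.int64), rec.get("mnemonic")
        )
    return ReferenceDB(
        entries, meta["cutoff"], meta["min_len"], meta["max_len"], meta["n_excluded"]
    )


def write_hits_tsv(hits: HitList, path) -> None:
    """query_id, reference_id, rank, score (4 decimals)."""
    with open(path, "w") as fh:
        fh.write("query_id\treference_id\trank\tscore\n")
        for rank, (ref_id, score) in enumerate(hits.hits, start=1):
            fh.write(f"{hits.query_id}\t{ref_id}\t{rank}\t{score:.4f}\n")
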