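"""Graphlet-signature similarity and order-preserving contact-graph alignment.

Two contact graphs are compared by (1) computing, for every residue node,
its graphlet degree signature — the counts of the 15 automorphism orbits of
the 9 connected graphlets on 2–4 nodes; (2) scoring node pairs by a
weighted log-scale signature distance; and (3) aligning the two residue
orders with a global dynamic program that maximizes the summed similarity
of matched nodes.  The alignment score is normalized by the larger node
count, so it ranges over [0, 1] with 1.0 for identical graphs.

Orbit numbering follows the standard catalogue: 0 edge; 1–2 3-path
(end, middle); 3 triangle; 4–5 4-path (end, middle); 6–7 3-star (leaf,
center); 8 4-cycle; 9–11 tailed triangle (tail end, triangle rim,
junction); 12–13 diamond (rim, hub); 14 complete K4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_map import ContactGraph
from .errors import DegenerateInputError, InputError

N_ORBITS = 15

#: For each orbit, the number of orbits whose counts it depends on (itself
#: included); these yield the signature weights w_i = 1 - log(o_i)/log(73).
ORBIT_DEPENDENCY_COUNTS = np.array([1, 2, 2, 2, 3, 4, 3, 3, 4, 3, 4, 4, 4, 4, 3], dtype=float)

ORBIT_WEIGHTS = 1.0 - np.log(ORBIT_DEPENDENCY_COUNTS) / np.log(73.0)


def count_orbits(graph: ContactGraph) -> np.ndarray:
    """Exact per-node orbit counts for orbits 0-14, shape (L, 15).

    Every connected induced subgraph on 2-4 nodes is enumerated exactly once
    (ESU-style expansion) and classified by its within-subgraph degree
    sequence; each participating node's orbit counter is incremented.
    Isolated nodes keep the zero vector.
    """
    L = graph.length
    adj = graph.adjacency_sets()
    counts = np.zeros((L, N_ORBITS), dtype=np.int64)

    def classify(sub: tuple[int, ...]) -> None:
        k = len(sub)
        if k == 2:
            counts[sub[0], 0] += 1
            counts[sub[1], 0] += 1
            return
        deg = [sum(1 for u in sub if u in adj[v]) for v in sub]
        if k == 3:
            if sum(deg) == 6:  # triangle
                for v in sub:
                    counts[v, 3] += 1
            else:  # 3-path
                for v, d in zip(sub, deg):
                    counts[v, 2 if d == 2 else 1] += 1
            return
        m2 = sum(deg)  # twice the edge count
        if m2 == 6:  # 3 edges: 4-path or 3-star
            if max(deg) == 3:
                for v, d in zip(sub, deg):
                    counts[v, 7 if d == 3 else 6] += 1
            else:
                for v, d in zip(sub, deg):
                    counts[v, 5 if d == 2 else 4] += 1
        elif m2 == 8:  # 4 edges: 4-cycle or tailed triangle
            if max(deg) == 2:
                for v in sub:
                    counts[v, 8] += 1
            else:
                for v, d in zip(sub, deg):
                    counts[v, 9 if d == 1 else (10 if d == 2 else 11)] += 1
        elif m2 == 10:  # diamond
            for v, d in zip(sub, deg):
                counts[v, 13 if d == 3 else 12] += 1
        else:  # m2 == 12: K4
            for v in sub:
                counts[v, 14] += 1

    # ESU: each connected induced subgraph with minimum node v is generated
    # exactly once by extending with exclusive neighbours greater than v.
    def extend(sub: list[int], ext: set[int], v: int) -> None:
        while ext:
            w = ext.pop()
            # exclusive neighbourhood of w w.r.t. sub (w not yet included)
            neighborhood = set().union(*(adj[u] for u in sub))
            new_ext = ext | {
                u for u in adj[w] if u > v and u not in sub and u not in neighborhood
            }
            sub.append(w)
            classify(tuple(sub))
            if len(sub) < 4:
                extend(sub, new_ext, v)
            sub.pop()

    for v in range(L):
        extend([v], {u for u in adj[v] if u > v}, v)
    return counts


def node_similarity(sig_u: np.ndarray, sig_v: np.ndarray) -> float:
    """Similarity in [0, 1] of two 15-orbit signatures: 1 minus the weighted
    mean of per-orbit log-scale distances."""
    u = np.asarray(sig_u, dtype=float)
    v = np.asarray(sig_v, dtype=float)
    if u.shape != (N_ORBITS,) or v.shape != (N_ORBITS,):
        raise InputError(f"signatures must have length {N_ORBITS}")
    dist = np.abs(np.log(u + 1.0) - np.log(v + 1.0)) / np.log(np.maximum(u, v) + 2.0)
    return float(1.0 - (ORBIT_WEIGHTS * dist).sum() / ORBIT_WEIGHTS.sum())


def similarity_matrix(sigs1: np.ndarray, sigs2: np.ndarray) -> np.ndarray:
    """Pairwise node similarities, shape (L1, L2); vectorized node_similarity."""
    a = np.asarray(sigs1, dtype=float)[:, None, :]
    b = np.asarray(sigs2, dtype=float)[None, :, :]
    dist = np.abs(np.log(a + 1.0) - np.log(b + 1.0)) / np.log(np.maximum(a, b) + 2.0)
    return 1.0 - (ORBIT_WEIGHTS * dist).sum(axis=2) / ORBIT_WEIGHTS.sum()


@dataclass(frozen=True)
class AlignmentResult:
    """Order-preserving node matching between two graphs and its score.

    ``mapping`` is a tuple of (i, j) 1-based node pairs, strictly increasing
    in both coordinates; ``score`` is the summed similarity of matched pairs
    divided by max(L1, L2), in [0, 1].
    """

    mapping: tuple
    score: float
    matched_similarity: float


def align_graphs(
    g1: ContactGraph,
    g2: ContactGraph,
    gap_score: float = 0.0,
    sigs1: np.ndarray | None = None,
    sigs2: np.ndarray | None = None,
) -> AlignmentResult:
    """Globally align two contact graphs preserving residue order.

    Needleman-Wunsch over the node orders with match score = graphlet
    signature similarity and ``gap_score`` per unmatched node.  Ties are
    broken toward matching, then toward the earliest (lexicographically
    smallest) mapping.  Precomputed signatures may be passed to skip
    re-counting.
    """
    if g1.length < 1 or g2.length < 1:
        raise DegenerateInputError("cannot align an empty graph")
    s1 = count_orbits(g1) if sigs1 is None else np.asarray(sigs1)
    s2 = count_orbits(g2) if sigs2 is None else np.asarray(sigs2)
    S = similarity_matrix(s1, s2)
    n1, n2 = S.shape

    dp = np.zeros((n1 + 1, n2 + 1))
    dp[0, :] = gap_score * np.arange(n2 + 1)
    dp[:, 0] = gap_score * np.arange(n1 + 1)
    if gap_score == 0.0:
        # left moves add nothing, so each row is a running maximum
        for i in range(1, n1 + 1):
            cand = np.maximum(dp[i - 1, 1:], dp[i - 1, :-1] + S[i - 1])
            dp[i, 1:] = np.maximum.accumulate(cand)
    else:
        for i in range(1, n1 + 1):
            row = dp[i]
            prev = dp[i - 1]
            for j in range(1, n2 + 1):
                row[j] = max(
                    prev[j - 1] + S[i - 1, j - 1],
                    prev[j] + gap_score,
                    row[j - 1] + gap_score,
                )

    # backtrace: prefer match, then advancing in g1, for a deterministic map
    tol = 1e-9
    i, j = n1, n2
    pairs: list[tuple[int, int]] = []
    matched = 0.0
    while i > 0 and j > 0:
        if dp[i, j] <= dp[i - 1, j - 1] + S[i - 1, j - 1] + tol:
            pairs.append((i, j))
            matched += S[i - 1, j - 1]
            i -= 1
            j -= 1
        elif dp[i, j] <= dp[i - 1, j] + gap_score + tol:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    score = matched / max(n1, n2)
    return AlignmentResult(tuple(pairs), float(min(score, 1.0)), float(matched))


def write_alignment(result: AlignmentResult, path) -> None:
    """Two-column matched-index TSV with the score in a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# score\t{result.score:.6f}\n")
        for i, j in result.mapping:
            fh.write(f"{i}\t{j}\n")
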