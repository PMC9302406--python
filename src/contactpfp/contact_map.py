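"""Contact graphs from distance-probability maps or coordinates.

A contact graph represents a protein as ordered residue nodes (1-based)
with an undirected edge for every residue pair whose representative atoms
(Cβ; Cα for glycine) are within a distance cutoff.  Graphs are built
either from a binned residue-residue distance probability map (distogram),
by thresholding the probability that a pair lies within the cutoff, or
directly from atomic coordinates.

Distogram layout convention: ``bin_edges`` holds the ascending finite bin
boundaries; channel ``k`` (``k < B-1``) covers ``(bin_edges[k],
bin_edges[k+1]]`` and the last channel is the open "no contact" bin beyond
``bin_edges[-1]``.  The default edges follow the 0.5 Å grid from 2 to 20 Å
used by modern distance predictors, giving 36 finite bins plus the open
bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, InputError

logger = logging.getLogger(__name__)

#: Default minimum sequence separation |i - j| for an edge.  Sequence-adjacent
#: residues are within any tested cutoff and carry no fold signal.
DEFAULT_MIN_SEPARATION = 2

#: Default probability threshold: a pair is "in contact" when the probability
#: of being at the cutoff distance or closer is 0.5 or larger.
DEFAULT_PROB_THRESHOLD = 0.5

_PROB_TOL = 1e-4


def trrosetta_bin_edges() -> np.ndarray:
    """Finite bin boundaries of the conventional distogram grid: 2–20 Å in 0.5 Å steps."""
    return np.arange(2.0, 20.0 + 0.25, 0.5)


@dataclass(frozen=True)
class DistogramMap:
    """Per-residue-pair binned distance probabilities for one protein.

    ``probabilities`` has shape (L, L, B) with B = len(bin_edges) finite-plus-open
    channels; each pair's channel vector sums to 1 and the array is symmetric
    in its first two axes.
    """

    protein_id: str
    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise InputError("bin_edges must be a 1-D ascending array of at least 2 distances")
        if probs.ndim != 3 or probs.shape[0] != probs.shape[1]:
            raise InputError(f"probabilities must be L x L x B, got shape {probs.shape}")
        if probs.shape[2] != len(edges):
            raise InputError(
                f"expected {len(edges)} probability channels "
                f"({len(edges) - 1} finite bins + open bin), got {probs.shape[2]}"
            )
        if probs.shape[0] < 1:
            raise InputError("distogram must cover at least one residue")
        if np.any(probs < -_PROB_TOL):
            raise InputError("negative bin probabilities")
        sums = probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=_PROB_TOL):
            bad = int(np.sum(~np.isclose(sums, 1.0, atol=_PROB_TOL)))
            raise InputError(f"bin probabilities must sum to 1 per pair; {bad} pairs violate this")
        if not np.allclose(probs, probs.transpose(1, 0, 2), atol=_PROB_TOL):
            raise InputError("distogram probabilities are asymmetric beyond tolerance")

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    def prob_within(self, cutoff: float) -> np.ndarray:
        """L x L matrix of P(distance <= cutoff); cutoff must lie on a bin edge."""
        idx = _edge_index(self.bin_edges, cutoff)
        return self.probabilities[:, :, :idx].sum(axis=2)


def _edge_index(edges: np.ndarray, cutoff: float) -> int:
    hits = np.nonzero(np.isclose(edges, cutoff, atol=1e-6))[0]
    if len(hits) == 0:
        below = edges[edges < cutoff]
        above = edges[edges > cutoff]
        lo = f"{below[-1]:g}" if len(below) else "none"
        hi = f"{above[0]:g}" if len(above) else "none"
        raise ConfigurationError(
            f"cutoff {cutoff:g} Å does not coincide with a distogram bin edge; "
            f"nearest edges are {lo} and {hi} Å"
        )
    return int(hits[0])


@dataclass(frozen=True)
class ContactGraph:
    """Undirected residue-contact graph with 1-based node indices.

    Edges are stored as a frozenset of sorted (i, j) tuples; every edge
    satisfies ``|i - j| >= min_separation``.
    """

    protein_id: str
    length: int
    cutoff: float
    edges: frozenset = field(default_factory=frozenset)
    min_separation: int = DEFAULT_MIN_SEPARATION

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", frozenset((min(i, j), max(i, j)) for i, j in self.edges)
        )
        if self.length < 1:
            raise InputError("contact graph needs at least one residue")
        if self.cutoff <= 0:
            raise InputError("cutoff must be positive")
        for i, j in self.edges:
            if i == j:
                raise InputError(f"self-edge at residue {i}")
            if not (1 <= i <= self.length and 1 <= j <= self.length):
                raise InputError(f"edge ({i},{j}) outside [1, {self.length}]")
            if abs(i - j) < self.min_separation:
                raise InputError(
                    f"edge ({i},{j}) violates minimum sequence separation {self.min_separation}"
                )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_sets(self) -> list[set[int]]:
        """Neighbour sets indexed 0..L-1 (node k at index k-1)."""
        adj: list[set[int]] = [set() for _ in range(self.length)]
        for i, j in self.edges:
            adj[i - 1].add(j - 1)
            adj[j - 1].add(i - 1)
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(1, self.length + 1))
        g.add_edges_from(self.edges)
        return g


def contacts_from_distogram(
    distogram: DistogramMap,
    cutoff: float,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactGraph:
    """Threshold a distogram into a contact graph.

    An edge (i, j) is created when |i - j| >= min_separation and the summed
    probability of all bins with upper edge <= cutoff is >= prob_threshold
    (inclusive: a probability of exactly the threshold is a contact).
    """
    if not (0.0 < prob_threshold <= 1.0):
        raise ConfigurationError(f"prob_threshold must be in (0, 1], got {prob_threshold}")
    within = distogram.prob_within(cutoff)
    L = distogram.length
    iu, ju = np.triu_indices(L, k=max(min_separation, 1))
    # inclusive threshold with a small tolerance so exact-0.5 float sums qualify
    mask = within[iu, ju] >= prob_threshold - 1e-9
    edges = frozenset((int(i) + 1, int(j) + 1) for i, j in zip(iu[mask], ju[mask]))
    return ContactGraph(distogram.protein_id, L, cutoff, edges, min_separation)


def contacts_from_coordinates(
    residue_positions: np.ndarray,
    cutoff: float,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    protein_id: str = "structure",
) -> ContactGraph:
    """Build a contact graph from one representative 3-D point per residue.

    ``residue_positions`` is (L, 3); rows with any NaN mark missing residues,
    which contribute no edges.
    """
    pos = np.asarray(residue_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise InputError(f"residue_positions must be (L, 3), got {pos.shape}")
    L = pos.shape[0]
    present = ~np.isnan(pos).any(axis=1)
    n_missing = int(L - present.sum())
    if n_missing:
        logger.warning("%s: %d residues without coordinates excluded from edges",
                       protein_id, n_missing)
    if int(present.sum()) < 2:
        raise DegenerateInputError("fewer than 2 resolvable residues")
    from scipy.spatial.distance import squareform, pdist

    idx = np.nonzero(present)[0]
    dmat = squareform(pdist(pos[idx]))
    edges = set()
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = int(idx[a]) + 1, int(idx[b]) + 1
            if j - i >= min_separation and dmat[a, b] <= cutoff:
                edges.add((i, j))
    return ContactGraph(protein_id, L, cutoff, frozenset(edges), min_separation)


def contact_precision(
    predicted: ContactGraph,
    reference: ContactGraph,
    mode: str = "all",
    pair_scores: dict | None = None,
    long_range_separation: int = 24,
) -> float:
    """Fraction of selected predicted contacts present in the reference.

    mode "all": every predicted edge counts (graphs share a cutoff, 12 Å in
    the standard benchmark).  mode "top_L5_long": rank candidate long-range
    pairs (separation >= ``long_range_separation``) by ``pair_scores`` and
    evaluate the floor(L/5) best against the reference (8 Å reference
    contacts in the standard benchmark).
    """
    if predicted.length != reference.length:
        raise InputError(
            f"length mismatch: predicted {predicted.length} vs reference {reference.length}"
        )
    ref = reference.edges
    if mode == "all":
        if not predicted.edges:
            return 0.0
        tp = len(predicted.edges & ref)
        return tp / len(predicted.edges)
    if mode == "top_L5_long":
        if pair_scores is None:
            raise InputError("mode 'top_L5_long' requires pair_scores")
        n_select = predicted.length // 5
        if n_select < 1:
            raise DegenerateInputError(f"L/5 < 1 for length {predicted.length}")
        candidates = [
            ((min(i, j), max(i, j)), s)
            for (i, j), s in pair_scores.items()
            if abs(i - j) >= long_range_separation
        ]
        candidates.sort(key=lambda kv: (-kv[1], kv[0]))
        selected = [p for p, _ in candidates[:n_select]]
        if not selected:
            return 0.0
        tp = sum(1 for p in selected if p in ref)
        return tp / len(selected)
    raise ConfigurationError(f"unknown precision mode {mode!r}")


# ---------------------------------------------------------------------------
# file formats


def write_edge_list(graph: ContactGraph, path) -> None:
    """Plain edge-list format: 'protein_id L cutoff min_separation' header,
    then one 'i j' pair per line, sorted."""
    with open(path, "w") as fh:
        fh.write(f"{graph.protein_id}\t{graph.length}\t{graph.cutoff:g}\t{graph.min_separation}\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{i} {j}\n")


def read_edge_list(path) -> ContactGraph:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3:
            raise InputError(f"{path}: malformed edge-list header")
        protein_id, length, cutoff = header[0], int(header[1]), float(header[2])
        min_sep = int(header[3]) if len(header) > 3 else DEFAULT_MIN_SEPARATION
        edges = set()
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise InputError(f"{path}: malformed edge line {line!r}")
            edges.add((int(parts[0]), int(parts[1])))
    return ContactGraph(protein_id, length, cutoff, frozenset(edges), min_sep)


_RR_HEADERS = ("PFRMAT", "TARGET", "AUTHOR", "REMARK", "METHOD", "MODEL", "END")


def read_casp_rr(
    path,
    cutoff: float | None = None,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    length: int | None = None,
    protein_id: str | None = None,
) -> ContactGraph:
    """Read a CASP-RR contact list into a contact graph.

    Records are 'i j d_low d_high probability'.  A record becomes an edge when
    its probability is >= prob_threshold, its upper distance bound is <= cutoff
    (when a cutoff is given; otherwise the maximum d_high in the file is used
    as the graph's cutoff), and the separation constraint holds.  The length
    is taken from embedded sequence lines when present, else from the largest
    residue index, unless given explicitly.
    """
    records: list[tuple[int, int, float, float, float]] = []
    seq_len = 0
    target = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            token = line.split()[0].upper()
            if token in _RR_HEADERS:
                if token == "TARGET" and len(line.split()) > 1:
                    target = line.split()[1]
                continue
            parts = line.split()
            if len(parts) == 1 and parts[0].isalpha():
                seq_len += len(parts[0])  # sequence line
                continue
            if len(parts) != 5:
                raise InputError(f"{path}: malformed RR record {line!r}")
            i, j = int(parts[0]), int(parts[1])
            d_lo, d_hi, prob = float(parts[2]), float(parts[3]), float(parts[4])
            records.append((i, j, d_lo, d_hi, prob))
    if not records and seq_len == 0 and length is None:
        raise DegenerateInputError(f"{path}: no contact records")
    max_idx = max((max(i, j) for i, j, *_ in records), default=0)
    L = length or seq_len or max_idx
    if max_idx > L:
        raise InputError(f"{path}: residue index {max_idx} exceeds length {L}")
    eff_cutoff = cutoff if cutoff is not None else max((r[3] for r in records), default=8.0)
    edges = {
        (min(i, j), max(i, j))
        for i, j, _, d_hi, prob in records
        if prob >= prob_threshold - 1e-9 and d_hi <= eff_cutoff + 1e-6
        and abs(i - j) >= min_separation
    }
    pid = protein_id or target or "query"
    return ContactGraph(pid, L, eff_cutoff, frozenset(edges), min_separation)


def write_casp_rr(graph: ContactGraph, path, probability: float = 1.0) -> None:
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        fh.write(f"TARGET {graph.protein_id}\n")
        fh.write("MODEL 1\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{i} {j} 0 {graph.cutoff:g} {probability:.3f}\n")
        fh.write("END\n")


def residue_positions_from_structure(path, chain_id: str | None = None) -> np.ndarray:
    """Extract one representative point per residue (Cβ; Cα for glycine) from
    a PDB or mmCIF file.  Residues lacking both atoms get NaN coordinates."""
    from Bio.PDB import MMCIFParser, PDBParser

    path = str(path)
    parser = (
        MMCIFParser(QUIET=True)
        if path.endswith((".cif", ".mmcif"))
        else PDBParser(QUIET=True)
    )
    structure = parser.get_structure("s", path)
    model = next(structure.get_models())
    chain = model[chain_id] if chain_id is not None else next(model.get_chains())
    positions = []
    for residue in chain:
        if residue.id[0] != " ":  # skip heteroatoms and waters
            continue
        atom = None
        if "CB" in residue:
            atom = residue["CB"]
        elif "CA" in residue:
            if residue.get_resname() != "GLY":
                logger.warning("residue %s lacks CB; using CA", residue.id)
            atom = residue["CA"]
        if atom is None:
            logger.warning("residue %s has no representative atom; dropped", residue.id)
            positions.append([math.nan] * 3)
        else:
            positions.append(list(atom.coord))
    return np.asarray(positions, dtype=float)
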