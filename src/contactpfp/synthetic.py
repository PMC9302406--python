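"""Synthetic fixtures: contact graphs, distograms, ontologies, annotations.

The generator emulates the shape of the real inputs — near-diagonal "band"
contacts as in helical packs, antidiagonal hairpin blocks as in β-sheets,
and random background graphs — together with a small is_a-only term DAG
and family-structured annotations, so that retrieval and function transfer
are learnable end to end without downloads.  One global seed fans out to
per-component streams, making every artifact reproducible bit for bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .contact_map import (
    DEFAULT_MIN_SEPARATION,
    ContactGraph,
    DistogramMap,
    trrosetta_bin_edges,
)
from .errors import DegenerateInputError, InputError
from .go_annotation import NAMESPACES, AnnotationSet, Ontology, load_ontology

TOPOLOGIES = ("band", "antidiagonal", "random")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic universe.

    Defaults give 30 template families of realistic single-domain size with
    lightly perturbed queries (2% of pair slots), a 3-level ontology per
    namespace, and a handful of direct terms per protein.
    """

    seed: int = 0
    length_range: tuple = (50, 120)
    topology: str = "band"
    band_width: int = 4
    block_count: int = 3
    edge_density: float = 0.08
    perturbation_rate: float = 0.0
    min_separation: int = DEFAULT_MIN_SEPARATION
    n_families: int = 30
    members_per_family: int = 2
    query_perturbation: float = 0.02
    terms_per_level: int = 4
    ontology_depth: int = 3
    annotations_per_protein: int = 3

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise InputError(f"topology must be one of {TOPOLOGIES}")
        if not (0.0 <= self.perturbation_rate <= 1.0):
            raise InputError("perturbation rate must be in [0, 1]")


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    # one global seed fans out to independent per-component streams
    return np.random.default_rng([spec_seed, stream])


def _eligible_slots(length: int, min_separation: int):
    return [(i, j) for i in range(1, length + 1)
            for j in range(i + min_separation, length + 1)]


def band_graph(length: int, width: int, min_separation: int = DEFAULT_MIN_SEPARATION,
               protein_id: str = "band") -> ContactGraph:
    """Helix-pack-like template: edges exactly {(i, j): min_sep <= j-i <= width}."""
    edges = {(i, j) for i in range(1, length + 1)
             for j in range(i + min_separation, min(i + width, length) + 1)}
    return ContactGraph(protein_id, length, 12.0, frozenset(edges), min_separation)


def antidiagonal_graph(length: int, block_count: int, block_width: int = 2,
                       min_separation: int = DEFAULT_MIN_SEPARATION,
                       protein_id: str = "sheet") -> ContactGraph:
    """Sheet-like template: hairpin blocks of contacts along anti-diagonals
    (i + j approximately constant)."""
    edges = set()
    centers = np.linspace(length // 2, 2 * length - length // 4, block_count).astype(int)
    for c in centers:
        for i in range(1, length + 1):
            for j in range(i + min_separation, length + 1):
                if abs((i + j) - int(c)) <= block_width:
                    edges.add((i, j))
    return ContactGraph(protein_id, length, 12.0, frozenset(edges), min_separation)


def random_graph(length: int, density: float, rng: np.random.Generator,
                 min_separation: int = DEFAULT_MIN_SEPARATION,
                 protein_id: str = "random") -> ContactGraph:
    edges = {slot for slot in _eligible_slots(length, min_separation)
             if rng.random() < density}
    return ContactGraph(protein_id, length, 12.0, frozenset(edges), min_separation)


def generate_contact_graph(spec: SyntheticSpec, protein_id: str = "synthetic",
                           length: int | None = None,
                           stream: int = 1) -> ContactGraph:
    """Deterministic template graph per spec (plus its perturbation rate)."""
    rng = _rng(spec.seed, stream)
    L = length if length is not None else int(rng.integers(*spec.length_range))
    if L < 3:
        raise DegenerateInputError(f"synthetic graph length {L} < 3")
    if spec.topology == "band":
        g = band_graph(L, spec.band_width, spec.min_separation, protein_id)
    elif spec.topology == "antidiagonal":
        g = antidiagonal_graph(L, spec.block_count, 2, spec.min_separation, protein_id)
    else:
        g = random_graph(L, spec.edge_density, rng, spec.min_separation, protein_id)
    if spec.perturbation_rate > 0:
        g = perturb_graph(g, spec.perturbation_rate, int(rng.integers(2**31)))
    return g


def perturb_graph(g: ContactGraph, rate: float, seed: int) -> ContactGraph:
    """Flip each eligible pair slot independently with probability ``rate``
    (rate 1 yields the complement within eligible slots); separation preserved."""
    if not (0.0 <= rate <= 1.0):
        raise InputError("perturbation rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = set(g.edges)
    for slot in _eligible_slots(g.length, g.min_separation):
        if rng.random() < rate:
            edges.symmetric_difference_update({slot})
    return replace(g, edges=frozenset(edges))


def generate_distogram(
    g: ContactGraph,
    contact_prob: float = 0.9,
    noncontact_prob: float = 0.1,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
) -> DistogramMap:
    """Distogram whose thresholding at the graph's cutoff recovers ``g``.

    Pairs with an edge receive total probability ``contact_prob`` on bins at
    or below the cutoff and the rest above; non-edges the reverse.  Within
    each side the mass is split with random (seeded) proportions, so bins are
    non-trivial while pair totals stay exact and symmetric.
    """
    if not (0.0 <= noncontact_prob <= 1.0 and 0.0 <= contact_prob <= 1.0):
        raise InputError("probabilities must lie in [0, 1]")
    edges = bin_edges if bin_edges is not None else trrosetta_bin_edges()
    edges = np.asarray(edges, dtype=float)
    n_below = int(np.sum(edges <= g.cutoff + 1e-6)) - 1  # finite bins with upper edge <= cutoff
    if n_below < 1:
        raise InputError(f"cutoff {g.cutoff} below the first bin edge")
    B = len(edges)  # finite bins + open bin
    n_above = B - n_below
    rng = np.random.default_rng(seed)
    L = g.length
    probs = np.zeros((L, L, B))
    edge_set = g.edges
    for i in range(1, L + 1):
        for j in range(i, L + 1):
            if i == j:
                vec = np.zeros(B)
                vec[0] = 1.0
            else:
                below_total = contact_prob if (i, j) in edge_set else noncontact_prob
                w_lo = rng.dirichlet(np.ones(n_below))
                w_hi = rng.dirichlet(np.ones(n_above))
                vec = np.concatenate([w_lo * below_total, w_hi * (1.0 - below_total)])
            probs[i - 1, j - 1] = vec
            probs[j - 1, i - 1] = vec
    return DistogramMap(g.protein_id, edges, probs)


# ---------------------------------------------------------------------------
# ontology + annotations


def generate_obo_text(spec: SyntheticSpec) -> str:
    """Deterministic OBO 1.2 document: per namespace one root and
    ``ontology_depth`` levels of ``terms_per_level`` terms, is_a only."""
    rng = _rng(spec.seed, 7)
    lines = ["format-version: 1.2", "ontology: contactpfp-synthetic", ""]
    counter = 1
    for ns in NAMESPACES:
        levels: list[list[str]] = []
        root = f"GO:{counter:07d}"
        counter += 1
        lines += [f"[Term]", f"id: {root}", f"name: {ns} root", f"namespace: {ns}", ""]
        levels.append([root])
        for depth in range(1, spec.ontology_depth + 1):
            level = []
            for _ in range(spec.terms_per_level):
                term = f"GO:{counter:07d}"
                counter += 1
                n_parents = 1 + int(rng.random() < 0.3 and depth > 1)
                parents = rng.choice(levels[-1], size=min(n_parents, len(levels[-1])),
                                     replace=False)
                lines += [f"[Term]", f"id: {term}",
                          f"name: {ns} term {term[-4:]}", f"namespace: {ns}"]
                lines += [f"is_a: {p} ! parent" for p in sorted(parents)]
                lines.append("")
                level.append(term)
            levels.append(level)
    return "\n".join(lines)


def generate_ontology_and_annotations(
    spec: SyntheticSpec,
) -> tuple[Ontology, AnnotationSet]:
    """Ontology plus leaf-biased direct annotations for the benchmark's DB
    proteins; see generate_benchmark for the full universe."""
    bench = generate_benchmark(spec)
    return bench.ontology, bench.annotations


@dataclass
class SyntheticBenchmark:
    """A fully seeded study universe: a reference DB of template-family
    graphs, perturbed query graphs, the term DAG, direct annotations of DB
    proteins, and direct truth for the queries."""

    spec: SyntheticSpec
    db_graphs: list
    query_graphs: list
    db_family: dict
    query_family: dict
    obo_text: str
    ontology: Ontology
    annotations: AnnotationSet
    truth: AnnotationSet
    family_terms: dict = field(default_factory=dict)


def generate_benchmark(spec: SyntheticSpec) -> SyntheticBenchmark:
    """Generate ``n_families`` template families.

    Each family has a deterministic template graph (topology cycling through
    band / antidiagonal / random with varied sizes), ``members_per_family``
    database entries (the template plus lightly perturbed siblings) and one
    query perturbed at ``query_perturbation``.  Families carry shared
    leaf-biased GO terms, so same-family proteins share direct annotations.
    """
    rng = _rng(spec.seed, 11)
    ann_rng = _rng(spec.seed, 13)
    obo_text = generate_obo_text(spec)
    ontology = load_ontology(io.StringIO(obo_text))
    # leaf-biased vocabulary: terms at maximum depth from each root
    depth_of: dict[str, int] = {}
    for term in sorted(ontology.graph.nodes):
        anc = ontology.ancestors(term)
        depth_of[term] = len(anc)
    max_depth = max(depth_of.values())
    leaves = [t for t, d in depth_of.items() if d >= max_depth - 1]
    mid = [t for t, d in depth_of.items() if 0 < d < max_depth - 1]

    db_graphs, query_graphs = [], []
    db_family: dict[str, int] = {}
    query_family: dict[str, int] = {}
    annotations: dict[str, set[str]] = {}
    truth: dict[str, set[str]] = {}
    family_terms: dict[int, set[str]] = {}

    # distinct folds by construction: one length per family (no replacement
    # when the range allows) and a redraw guard against duplicate templates
    lo, hi = spec.length_range
    span = hi - lo
    if span >= spec.n_families:
        lengths = lo + rng.permutation(span)[: spec.n_families]
    else:
        lengths = rng.integers(lo, hi, size=spec.n_families)
    seen_templates: set = set()

    for fam in range(spec.n_families):
        topology = TOPOLOGIES[fam % len(TOPOLOGIES)]
        length = int(lengths[fam])
        for _ in range(20):
            if topology == "band":
                width = int(rng.integers(3, 7))
                template = band_graph(length, width, spec.min_separation)
            elif topology == "antidiagonal":
                template = antidiagonal_graph(length, int(rng.integers(2, 5)), 2,
                                              spec.min_separation)
            else:
                template = random_graph(length, float(rng.uniform(0.04, 0.12)), rng,
                                        spec.min_separation)
            key = (length, frozenset(template.edges))
            if key not in seen_templates:
                seen_templates.add(key)
                break
        # family terms: a couple of leaves per namespace plus one mid-level term
        fam_terms = set(map(str, ann_rng.choice(leaves, size=spec.annotations_per_protein,
                                                replace=False)))
        if mid:
            fam_terms.add(str(ann_rng.choice(mid)))
        family_terms[fam] = fam_terms

        for m in range(spec.members_per_family):
            ref_id = f"T{fam:03d}{chr(ord('A') + m)}_REF"
            g = template if m == 0 else perturb_graph(
                template, 0.01, int(rng.integers(2**31)))
            db_graphs.append(replace(g, protein_id=ref_id))
            db_family[ref_id] = fam
            noise = {str(ann_rng.choice(leaves))} if ann_rng.random() < 0.5 else set()
            annotations[ref_id] = set(fam_terms) | noise

        query_id = f"Q{fam:03d}_QUERY"
        q = perturb_graph(template, spec.query_perturbation, int(rng.integers(2**31)))
        query_graphs.append(replace(q, protein_id=query_id))
        query_family[query_id] = fam
        truth[query_id] = set(fam_terms)

    return SyntheticBenchmark(
        spec=spec,
        db_graphs=db_graphs,
        query_graphs=query_graphs,
        db_family=db_family,
        query_family=query_family,
        obo_text=obo_text,
        ontology=ontology,
        annotations=AnnotationSet(annotations),
        truth=AnnotationSet(truth),
        family_terms=family_terms,
    )


def write_fixtures(out_dir, spec: SyntheticSpec, n_distograms: int = 2) -> dict:
    """Emit the benchmark to disk: edge lists + CASP-RR graphs, a few query
    distograms (npz), the OBO file, annotation TSV and truth TSV.  Returns a
    manifest of written paths."""
    from pathlib import Path

    from .contact_map import write_casp_rr, write_edge_list

    out = Path(out_dir)
    (out / "db").mkdir(parents=True, exist_ok=True)
    (out / "queries").mkdir(exist_ok=True)
    bench = generate_benchmark(spec)
    manifest = {"db": [], "queries": [], "distograms": []}
    for g in bench.db_graphs:
        p = out / "db" / f"{g.protein_id}.edges"
        write_edge_list(g, p)
        manifest["db"].append(str(p))
    for g in bench.query_graphs:
        p = out / "queries" / f"{g.protein_id}.rr"
        write_casp_rr(g, p)
        manifest["queries"].append(str(p))
    for g in bench.query_graphs[:n_distograms]:
        d = generate_distogram(g, seed=spec.seed)
        p = out / "queries" / f"{g.protein_id}.npz"
        np.savez_compressed(p, bin_edges=d.bin_edges, probabilities=d.probabilities,
                            protein_id=g.protein_id)
        manifest["distograms"].append(str(p))
    (out / "ontology.obo").write_text(bench.obo_text)
    with open(out / "annotations.tsv", "w") as fh:
        for pid in sorted(bench.annotations.annotations):
            for t in sorted(bench.annotations.annotations[pid]):
                fh.write(f"{pid}\t{t}\tIEA\tsynthetic\n")
    with open(out / "truth.tsv", "w") as fh:
        for pid in sorted(bench.truth.annotations):
            for t in sorted(bench.truth.annotations[pid]):
                fh.write(f"{pid}\t{t}\tEXP\tsynthetic\n")
    manifest["obo"] = str(out / "ontology.obo")
    manifest["annotations"] = str(out / "annotations.tsv")
    manifest["truth"] = str(out / "truth.tsv")
    return manifest


def read_distogram_npz(path) -> DistogramMap:
    data = np.load(path, allow_pickle=False)
    return DistogramMap(str(data["protein_id"]), data["bin_edges"], data["probabilities"])
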