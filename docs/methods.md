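# Methods

## Contact graphs

A protein of length L is represented as an undirected graph on the ordered
residue set {1..L}. From a distogram — an L×L×B array of per-pair
probabilities over distance bins — an edge (i, j) is created when the
summed probability of all bins with upper edge ≤ cutoff is at least the
probability threshold (default 0.5, inclusive) and |i − j| ≥
`min_separation`. The default bin grid is the 0.5 Å ladder from 2 to
20 Å used by modern distance predictors (36 finite bins plus one open
"no contact" bin); in this package the finite bins come first and the open
bin is the last channel. The cutoff must coincide with a bin edge —
asking for, say, 9.2 Å on a 0.5 Å grid is a configuration error that
names the two nearest edges, because no sum of whole bins can represent
it.

Parameters that matter:

- **cutoff** (Å, default 12): larger cutoffs connect more residue pairs;
  12 Å together with top-2 hit selection is the best-performing
  configuration and is the package default.
- **prob_threshold** (default 0.5): a pair is a contact when the mass at
  or below the cutoff reaches this value; the boundary is inclusive.
- **min_separation** (residues, default 2): |i−j| < 2 pairs are excluded,
  since sequence-adjacent residues are within any tested cutoff and carry
  no fold information. Configurable because conventions differ between
  contact-prediction pipelines.

From coordinates, the representative point is Cβ (Cα for glycine);
residues with no representative atom are dropped from edge formation with
a warning. Contact-precision metrics support two modes: all predicted
contacts against a same-cutoff reference, and the floor(L/5)
highest-confidence long-range pairs (separation ≥ 24) against an 8 Å
reference.

## Graphlet-signature alignment

The graph-comparison contract is: a score in [0, 1], 1.0 exactly for
identical graphs, sensitive to local topology, computed by aligning the
two residue orders. The realization here:

- **Signatures.** For every node, exact counts of the 15 automorphism
  orbits of the 9 connected graphlets on 2–4 nodes, computed by
  enumerating each connected induced subgraph exactly once (ESU-style
  expansion) and classifying it by its internal degree sequence. Orbit 0
  is the node degree. Five-node graphlets (orbits 15–72) are out of
  scope; with contact graphs of hundreds of nodes the 2–4-node orbits
  already separate folds well at a fraction of the cost.
- **Node similarity.** 1 minus a weighted mean of per-orbit log-scale
  distances |log(u+1) − log(v+1)| / log(max(u,v)+2), with weights
  w_i = 1 − log(o_i)/log(73), where o_i is the number of orbits affecting
  orbit i (the standard dependency counts [1,2,2,2,3,4,3,3,4,3,4,4,4,4,3]
  for orbits 0–14). The weights damp the heavily correlated higher
  orbits.
- **Alignment.** Global Needleman–Wunsch over the two node orders;
  matching residues i↔j adds their signature similarity, unmatched nodes
  add `gap_score` (default 0). The reported score is the summed
  similarity of matched pairs divided by max(L1, L2), so it is symmetric,
  bounded by 1, and penalizes length mismatch. With gap 0 each DP row is
  a running maximum, so the fill is vectorized. Backtrace ties prefer
  matching over gapping, then an earlier gap in the first graph, giving
  one deterministic optimal mapping.

Scores from this realization are internally consistent but not
numerically interchangeable with other graphlet-alignment tools; the
published two-hit worked example therefore enters the pipeline as printed
similarity scores (0.733, 0.658) feeding the transfer stage, which is
exactly how downstream scoring consumes any comparison backend.

## Reference database and hit selection

The database keeps one contact graph plus its precomputed signature per
reference protein. Sequences shorter than 20 or longer than 2000 residues
are excluded; the bounds are inclusive (20 and 2000 are retained) since
the exclusion is phrased strictly. Ortholog de-duplication keeps one
entry per UniProt mnemonic CODE prefix, choosing the lexicographically
smallest full id for determinism. Persistence is a single JSON archive of
edge lists, signature arrays and metadata.

Hit selection schemes, applied after removing an externally supplied
exclusion list (the query itself and trivial sequence matches; this
package consumes such lists, it never computes E-values):

- **score_threshold** (≥ 0.5 in the base protocol),
- **top_n** (default N = 2 — the best configuration; by default no score
  floor is applied on top, since top-N selection is defined regardless of
  score, with an optional flag to add one),
- **z_score**: z = (s − μ)/σ with μ, σ (population) over the query's full
  post-exclusion hit list; σ = 0 is an error advising another scheme.

## GO handling and transfer

The OBO parser (via obonet) maps alt_ids to canonical ids, drops obsolete
terms keeping their replaced_by redirects, and rejects cyclic is_a /
part_of structure. Propagation closes each protein's term set under is_a
and part_of within the term's namespace; regulates relations are not
followed and namespace roots are removed as uninformative (the common
evaluation convention). Evidence filtering supports all / experimental /
no-IEA, defaulting to all because including electronically inferred
annotations raises transfer accuracy.

Term scoring sums the similarity scores of selected hits carrying the
term; hits contribute their direct annotations by default, with a flag to
close hit annotations under ancestry first (the protocol leaves this
open). Normalization divides by the per-protein maximum — one global
maximum across namespaces, matching the single-formula definition, with a
per-namespace mode available. The uniform baseline mode assigns 1.0 to
every term found in the top 10 hits. Ensembling averages normalized
scores across methods with absence counted as 0, the only reading of
"simply averaged" consistent with methods emitting different term sets.

## Evaluation

Thresholds are scanned on the 0.01 grid over (0, 1]. At each threshold
the predicted set is the ancestor closure of the terms scoring at or
above it (equivalently: scores are propagated with max before
thresholding). Precision is averaged over proteins with at least one
predicted term (a strict mode averaging over all proteins is a flag);
recall over all benchmark proteins with nonempty truth. The smallest
optimizing threshold is reported. Smin uses information content in bits
from the reference corpus itself: ic(t) = −log2(count(t)/n_ns) with n_ns
the number of proteins annotated in t's namespace, and −log2(1/(n+1)) as
an add-one guard for unseen terms. Smin is reported unnormalized (mean
per protein). Win counts compare two per-protein F vectors; only strict
inequalities count, ties are reported separately.

## Synthetic data

The generator emulates the *shape* of the real inputs: band topologies
(edges {(i,j): min_sep ≤ j−i ≤ w}) mimic near-diagonal helix-pack
contacts, antidiagonal blocks mimic β-hairpin contact stripes, and random
graphs provide unstructured controls. A benchmark universe consists of
`n_families` (default 30) distinct template folds — distinct by
construction: per-family lengths are drawn without replacement and
duplicate templates are redrawn — each contributing database members
(the template plus 1%-perturbed siblings) and one query perturbed at 2%
of eligible pair slots, which empirically lowers self-similarity to
roughly 0.8, a realistic level for a good structure prediction.
Perturbation flips each eligible slot independently, so rate 1 yields the
complement. Distograms place the required total mass below/above the
cutoff per pair with seeded random within-side proportions, so
thresholding recovers the generating graph exactly while individual bins
are non-trivial. The ontology fixture is an is_a-only DAG (three
namespaces, default depth 3 × 4 terms per level) to keep propagation
hand-checkable; families share leaf-biased term sets so transfer is
learnable, plus per-member noise terms.

What passing on this universe does **not** show: real fold statistics,
trRosetta error modes, disordered regions, or annotation sparsity of real
corpora. It shows that retrieval ranks structurally similar graphs above
dissimilar ones under controlled noise, and that similarity-weighted
transfer beats random scoring — directional correctness, not benchmark
numbers.

One global seed fans out to fixed per-component streams, so every
artifact (including OBO bytes) is reproducible bit for bit.

## Numerical choices and problem sizes

- Probability comparisons against thresholds use a 1e-9 absolute
  tolerance so exact-0.5 sums of floating bins qualify as contacts.
- Distogram validation: per-pair bin sums within 1e-4 of 1; symmetry
  within 1e-4.
- DP backtrace uses a 1e-9 tolerance when identifying optimal moves.
- Degenerate inputs error early: empty graphs, empty databases, L/5 < 1
  in top-L/5 precision, σ = 0 under Z-score selection, empty ic corpora.
- Test and acceptance workloads use the 30-family universe (60 database
  graphs, 30 queries, lengths 50–120) and brute-force oracles on graphs
  of ≤ 10 nodes (orbit counts) and ≤ 6 nodes (alignments) — sizes chosen
  so exhaustive enumeration stays exact yet cheap.

## Known limitations

- Alignment is strictly sequence-order-preserving; circular permutations
  and domain swaps score poorly by design (non-sequential alignment is a
  non-goal).
- Scores are not calibrated probabilities; only their ranking and the
  per-protein normalization are meaningful.
- The graphlet vocabulary stops at 4 nodes; very large dense graphs with
  identical local structure can tie.
- Everything downstream trusts the contact predictor: systematically
  wrong distograms (e.g. for intrinsically disordered proteins) produce
  confidently wrong transfers, and no disorder filter is included.
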