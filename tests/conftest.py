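import io

import numpy as np
import pytest

from contactpfp.contact_map import ContactGraph
from contactpfp.go_annotation import load_ontology
from contactpfp.synthetic import SyntheticSpec, generate_benchmark


def make_graph(edges, length, protein_id="g", cutoff=8.0, min_separation=1):
    return ContactGraph(protein_id, length, cutoff, frozenset(edges), min_separation)


def random_contact_graph(rng, max_nodes=10, p=None, protein_id="r"):
    L = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.8)) if p is None else p
    edges = {
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + 1, L + 1)
        if rng.random() < p
    }
    return make_graph(edges, L, protein_id)


MINI_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: mf root
namespace: molecular_function

[Term]
id: GO:0000002
name: binding
namespace: molecular_function
is_a: GO:0000001 ! mf root

[Term]
id: GO:0000003
name: ion binding
namespace: molecular_function
alt_id: GO:0000333
is_a: GO:0000002 ! binding

[Term]
id: GO:0000004
name: metal ion binding
namespace: molecular_function
is_a: GO:0000003 ! ion binding

[Term]
id: GO:0000005
name: obsolete thing
namespace: molecular_function
is_obsolete: true
replaced_by: GO:0000004

[Term]
id: GO:0000010
name: bp root
namespace: biological_process

[Term]
id: GO:0000011
name: transport
namespace: biological_process
is_a: GO:0000010 ! bp root

[Term]
id: GO:0000012
name: ion transport
namespace: biological_process
is_a: GO:0000011 ! transport
relationship: part_of GO:0000011 ! transport
"""


@pytest.fixture(scope="session")
def mini_ontology():
    return load_ontology(io.StringIO(MINI_OBO))


@pytest.fixture(scope="session")
def small_benchmark():
    """Six-family universe for fast unit tests."""
    return generate_benchmark(SyntheticSpec(seed=3, n_families=6, length_range=(40, 70)))


@pytest.fixture(scope="session")
def full_benchmark():
    """The 30-family study universe used by the end-to-end checks."""
    return generate_benchmark(SyntheticSpec(seed=7))
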