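import logging

import numpy as np
import pytest

from lineorf1.profiles import default_library
from lineorf1.synthetic import SimulationConfig, generate_dataset

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def library_by_name(library):
    return {p.name: p for p in library}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140701)


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated dataset (20 taxa, 3 lineages, no transfer)."""
    return generate_dataset(SimulationConfig(seed=11))


def random_protein(rng, n):
    from lineorf1.io_formats import AA_LETTERS

    return "".join(AA_LETTERS[i] for i in rng.integers(0, 20, n))


@pytest.fixture(scope="session")
def random_tree_factory():
    """Random binary trees with branch lengths plus their additive matrices."""
    import dendropy

    from lineorf1.phylo import DistanceMatrix, PhyloTree

    def make(n, rng):
        nodes = []
        tns = dendropy.TaxonNamespace()
        ids = [f"t{i}" for i in range(n)]
        for lab in ids:
            node = dendropy.Node(taxon=tns.new_taxon(lab))
            nodes.append(node)
        active = list(nodes)
        while len(active) > 3:
            i, j = sorted(rng.choice(len(active), 2, replace=False))
            b, a = active.pop(j), active.pop(i)
            parent = dendropy.Node()
            parent.add_child(a)
            parent.add_child(b)
            a.edge.length = float(rng.uniform(0.1, 1.0))
            b.edge.length = float(rng.uniform(0.1, 1.0))
            active.append(parent)
        root = dendropy.Node()
        for a in active:
            root.add_child(a)
            a.edge.length = float(rng.uniform(0.1, 1.0))
        t = dendropy.Tree(seed_node=root, taxon_namespace=tns)
        t.is_rooted = False
        tree = PhyloTree(t)
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in tns}
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    values[i, j] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
        return tree, DistanceMatrix(tuple(ids), values)

    return make
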