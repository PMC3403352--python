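import dendropy
import numpy as np
import pytest

from traitscan.simulate import SimConfig, evolve_gene_content, simulate_species_tree


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by I/O and pipeline tests."""
    cfg = SimConfig(n_genomes=10, n_decoy_families=6, seed=42)
    tree = simulate_species_tree(cfg.n_genomes, cfg.seed)
    return evolve_gene_content(tree, cfg)


def random_additive_tree(n: int, rng: np.random.Generator):
    """Random unrooted binary tree with branch lengths in [0.1, 2].

    Used as the ground truth for additive-matrix recovery tests: the
    patristic distances of such a tree form an additive matrix.
    """
    labels = [f"L{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for label in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(label)
        nodes.append(nd)
    while len(nodes) > 3:
        i, j = sorted(int(x) for x in rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        a.edge.length = float(rng.uniform(0.1, 2.0))
        parent.add_child(b)
        b.edge.length = float(rng.uniform(0.1, 2.0))
        nodes.append(parent)
    for nd in nodes:
        tree.seed_node.add_child(nd)
        nd.edge.length = float(rng.uniform(0.1, 2.0))
    tree.is_rooted = False
    return tree, labels


def unrooted_topologies(labels):
    """Yield the Newick of every unrooted binary topology over ``labels``."""
    if len(labels) == 3:
        yield f"({labels[0]},{labels[1]},{labels[2]});"
        return
    for nwk in unrooted_topologies(labels[:-1]):
        base = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        n_edges = sum(1 for e in base.preorder_edge_iter() if e.head_node.parent_node)
        for pos in range(n_edges):
            tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
            edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
            edge = edges[pos]
            head = edge.head_node
            parent = head.parent_node
            mid = dendropy.Node()
            parent.remove_child(head)
            parent.add_child(mid)
            mid.add_child(head)
            leaf = dendropy.Node()
            leaf.taxon = tree.taxon_namespace.new_taxon(labels[-1])
            mid.add_child(leaf)
            yield tree.as_string(schema="newick", suppress_rooting=True)
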