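"""Distance phylogenetics: Kimura protein distances, neighbor joining,
bootstrap support, small-parsimony scoring and subtype partitioning.

Distances use the closed-form Kimura correction
``d = -ln(1 - p - 0.2 p^2)`` of the observed mismatch fraction p over
mutually ungapped columns (an approximation to the expected number of amino
acid replacements per position). Neighbor joining is the canonical
Saitou-Nei agglomeration, exact on additive matrices, with deterministic
tie-breaks (smallest row-index pair) and negative branch lengths clamped to
zero with the deficit moved to the sister branch. Parsimony is unit-cost
small parsimony (Fitch counts; computed by dynamic programming so that
multifurcating nodes and gap/missing leaves are scored exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import GAP, MSA

#: Kimura correction is undefined for p >= (sqrt(1.8) - 1) / 0.4 ~ 0.8541
KIMURA_CEILING_DEFAULT = 10.0


@dataclass
class GeneTree:
    """A family tree with optional bootstrap counts and subtype labels."""

    tree: dendropy.Tree
    n_replicates: int = 0
    bootstrap: dict[frozenset, int] = field(default_factory=dict)
    subtypes: dict[str, str] = field(default_factory=dict)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def protein_distance(
    msa: MSA, ceiling: float = KIMURA_CEILING_DEFAULT
) -> tuple[np.ndarray, list[str]]:
    """Kimura-corrected pairwise distance matrix of an alignment.

    p is the mismatch fraction over columns where both rows are ungapped;
    zero overlap is an error, and p beyond the correction's domain maps to
    ``ceiling`` with a warning.
    """
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(r) for r in msa.rows])
    gaps = arr == GAP
    n = len(msa.rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gaps[i] & ~gaps[j]
            overlap = int(both.sum())
            if overlap == 0:
                raise ValueError(
                    f"rows {msa.ids[i]} and {msa.ids[j]} share no ungapped columns"
                )
            p = float((arr[i, both] != arr[j, both]).mean())
            arg = 1.0 - p - 0.2 * p * p
            if arg <= 0.0:
                warnings.warn(
                    f"distance {msa.ids[i]}-{msa.ids[j]}: p={p:.3f} beyond the "
                    f"Kimura correction domain; using ceiling {ceiling}"
                )
                d = ceiling
            else:
                d = -np.log(arg)
            D[i, j] = D[j, i] = d
    return D, list(msa.ids)


def neighbor_joining(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Canonical neighbor joining; returns an unrooted dendropy tree.

    The final three lineages are joined at a trifurcating central node, the
    standard unrooted representation. On additive matrices with
    non-negative branch lengths the true topology and lengths are recovered
    exactly.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] != len(labels):
        raise ValueError("labels do not match matrix size")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for label in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(label)
        nodes.append(nd)
    work = D.copy()

    def clamp(length_a: float, length_b: float) -> tuple[float, float]:
        # negative branch clamped to 0, deficit moved to the sister branch
        if length_a < 0:
            length_b += length_a
            length_a = 0.0
        if length_b < 0:
            length_a += length_b
            length_b = 0.0
        return max(length_a, 0.0), max(length_b, 0.0)

    while work.shape[0] > 3:
        m = work.shape[0]
        r = work.sum(axis=1)
        Q = (m - 2) * work - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        i, j = min(
            (int(a), int(b))
            for a, b in zip(*np.nonzero(Q <= qmin + 1e-12))
            if a < b
        )
        li = 0.5 * work[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = work[i, j] - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = 0.5 * (work[i, :] + work[j, :] - work[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new = np.empty((m - 1, m - 1))
        new[: m - 2, : m - 2] = work[np.ix_(keep, keep)]
        new[m - 2, : m - 2] = new[: m - 2, m - 2] = new_row[keep]
        new[m - 2, m - 2] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        work = new

    # closed-form star resolution of the last three lineages
    d01, d02, d12 = work[0, 1], work[0, 2], work[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    center = tree.seed_node
    for nd, length in zip(nodes, lengths):
        center.add_child(nd)
        nd.edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Patristic (path-length) distances between the named leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(labels)
    out = np.zeros((n, n))
    taxa = [tns.get_taxon(lbl) for lbl in labels]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[i], taxa[j])
    return out


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits as canonical frozensets of leaf labels."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min((sorted(side), side), (sorted(other), other))[1]
        out.add(canon)
    return out


def bootstrap_support(
    msa: MSA,
    n_replicates: int = 100,
    seed: int = 0,
    ceiling: float = KIMURA_CEILING_DEFAULT,
) -> GeneTree:
    """Column-resampling bootstrap of the distance + NJ pipeline.

    Each replicate resamples alignment columns with replacement, rebuilds
    the NJ tree and records which of the original tree's bipartitions
    reappear. Counts annotate the internal node labels of the returned
    tree.
    """
    if len(msa.rows) < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    D, labels = protein_distance(msa, ceiling)
    tree = neighbor_joining(D, labels)
    original = bipartitions(tree)
    counts = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_cols
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep = MSA(ids=list(msa.ids), rows=rows)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Dr, _ = protein_distance(rep, ceiling)
        except ValueError:
            continue  # a pair lost all overlap; replicate supports nothing
        rep_bps = bipartitions(neighbor_joining(Dr, labels))
        for bp in original & rep_bps:
            counts[bp] += 1
    all_leaves = frozenset(labels)
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min((sorted(side), side), (sorted(other), other))[1]
        node.label = str(counts[canon])
    return GeneTree(tree=tree, n_replicates=n_replicates, bootstrap=counts)


def parsimony_score(msa: MSA, tree: dendropy.Tree) -> int:
    """Unit-cost small-parsimony changes summed over columns.

    Gaps (and X) are treated as missing: they contribute no state and no
    cost. Leaf set must equal the MSA IDs.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_labels != set(msa.ids):
        raise ValueError("tree leaves do not match MSA sequence IDs")
    row_of = {sid: row for sid, row in zip(msa.ids, msa.rows)}
    postorder = list(tree.postorder_node_iter())
    total = 0
    INF = 10**9
    for col in range(msa.n_cols):
        observed = sorted(
            {
                row_of[lf.taxon.label][col]
                for lf in tree.leaf_node_iter()
                if row_of[lf.taxon.label][col] not in (GAP, "X")
            }
        )
        if len(observed) < 2:
            continue
        state_idx = {s: i for i, s in enumerate(observed)}
        k = len(observed)
        cost: dict[int, list[int]] = {}
        for node in postorder:
            if node.is_leaf():
                ch = row_of[node.taxon.label][col]
                if ch in (GAP, "X"):
                    cost[id(node)] = [0] * k
                else:
                    c = [INF] * k
                    c[state_idx[ch]] = 0
                    cost[id(node)] = c
            else:
                c = [0] * k
                for child in node.child_nodes():
                    cc = cost[id(child)]
                    best = min(cc)
                    for s in range(k):
                        c[s] += min(cc[s], best + 1)
                cost[id(node)] = c
        total += min(cost[id(postorder[-1])])
    return total


def split_subtypes(
    tree: dendropy.Tree,
    rooting: str = "midpoint",
    reference_leaf: str | None = None,
    outgroup: str | None = None,
) -> dict[str, str]:
    """Two-way subtype labels from the rooted tree's basal split.

    The tree is midpoint-rooted (or rooted on ``outgroup``); the root's two
    child clades become the subtypes. Subtype I is the clade holding
    ``reference_leaf`` if given, otherwise the larger clade (ties broken by
    the lexicographically smallest leaf ID). A tree with zero total length
    has no midpoint: every leaf is labeled "unassigned" with a warning.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    total_length = sum(
        (e.length or 0.0) for e in tree.preorder_edge_iter() if e.head_node.parent_node
    )
    if total_length <= 0.0:
        warnings.warn("tree has zero total length; subtypes unassigned")
        return {lf: "unassigned" for lf in leaves}
    if len(leaves) == 2:
        first, second = sorted(leaves)
        if reference_leaf is not None and reference_leaf == second:
            return {second: "I", first: "II"}
        return {first: "I", second: "II"}
    rooted = tree.clone(depth=1)
    if rooting == "outgroup":
        if not outgroup:
            raise ValueError("outgroup rooting requires an outgroup leaf")
        og = rooted.find_node_with_taxon_label(outgroup)
        rooted.reroot_at_edge(og.edge, update_bipartitions=False)
    elif rooting == "midpoint":
        rooted.reroot_at_midpoint(update_bipartitions=False)
    else:
        raise ValueError(f"unknown rooting method {rooting!r}")
    children = rooted.seed_node.child_nodes()
    clade_a = sorted(lf.taxon.label for lf in children[0].leaf_iter())
    clade_b = sorted(set(leaves) - set(clade_a))
    if reference_leaf is not None:
        first_is_i = reference_leaf in clade_a
    elif len(clade_a) != len(clade_b):
        first_is_i = len(clade_a) > len(clade_b)
    else:
        first_is_i = min(clade_a) < min(clade_b)
    labels = {}
    for lf in clade_a:
        labels[lf] = "I" if first_is_i else "II"
    for lf in clade_b:
        labels[lf] = "II" if first_is_i else "I"
    return labels
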