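"""Independent brute-force oracles used to validate the core algorithms.

These deliberately avoid the package's dynamic-programming implementations:
local alignment is enumerated over monotone residue matchings, parsimony
over all internal-node state assignments, and the Fisher tail over the
hypergeometric support.
"""

import itertools
from math import comb


def local_align_oracle(a: str, b: str, S, index, gap_open: float, gap_extend: float) -> float:
    """Best local-alignment score by enumerating all monotone matchings.

    A local alignment is a set of aligned residue pairs with strictly
    increasing indices on both sequences; each internal unaligned run of
    length g on either side costs gap_open + g * gap_extend. The empty
    alignment scores 0.
    """
    best = 0.0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for rows in itertools.combinations(range(la), k):
            for cols in itertools.combinations(range(lb), k):
                score = sum(
                    S[index[a[r]], index[b[c]]] for r, c in zip(rows, cols)
                )
                for t in range(1, k):
                    gap_a = rows[t] - rows[t - 1] - 1
                    gap_b = cols[t] - cols[t - 1] - 1
                    if gap_a:
                        score -= gap_open + gap_extend * gap_a
                    if gap_b:
                        score -= gap_open + gap_extend * gap_b
                if score > best:
                    best = score
    return best


def parsimony_oracle(tree, states: dict[str, str | None]) -> int:
    """Minimum changes over all internal-node assignments (missing = None)."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    observed = sorted({s for s in states.values() if s is not None})
    if len(observed) < 2:
        return 0
    best = 10**9
    for assignment in itertools.product(observed, repeat=len(internals)):
        amap = {id(nd): s for nd, s in zip(internals, assignment)}
        cost = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            state = states[nd.taxon.label] if nd.is_leaf() else amap[id(nd)]
            parent = amap[id(nd.parent_node)]
            if state is not None and state != parent:
                cost += 1
        if cost < best:
            best = cost
    return best


def fisher_enrichment_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-tailed (enrichment) Fisher p by hypergeometric enumeration."""
    r1 = a + b
    r2 = c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if x >= a:
            total += comb(r1, x) * comb(r2, c1 - x)
    return total / denom
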