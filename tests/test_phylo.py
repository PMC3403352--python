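"""Distances, neighbor joining, bootstrap, parsimony, subtype split."""

import math

import dendropy
import numpy as np
import pytest

from traitscan.alignment import MSA
from traitscan.phylo import (
    bipartitions,
    bootstrap_support,
    neighbor_joining,
    parsimony_score,
    protein_distance,
    split_subtypes,
    tree_distance_matrix,
)


class TestProteinDistance:
    def test_identical_rows_distance_zero(self):
        msa = MSA(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        D, _ = protein_distance(msa)
        assert D[0, 1] == 0.0

    def test_kimura_correction_reference_point(self):
        # 1 mismatch in 10 columns: p = 0.1, d = -ln(0.898)
        msa = MSA(ids=["a", "b"], rows=["ACDEFGHIKL", "ACDEFGHIKV"])
        D, _ = protein_distance(msa)
        assert D[0, 1] == pytest.approx(-math.log(0.898), rel=1e-9)
        assert D[0, 1] == pytest.approx(0.1076, abs=2e-4)

    def test_distance_beyond_domain_hits_ceiling(self):
        msa = MSA(ids=["a", "b"], rows=["AAAAA", "CCCCC"])
        with pytest.warns(UserWarning, match="ceiling"):
            D, _ = protein_distance(msa)
        assert D[0, 1] == 10.0

    def test_zero_overlap_is_error(self):
        msa = MSA(ids=["a", "b"], rows=["AC--", "--DE"])
        with pytest.raises(ValueError, match="no ungapped"):
            protein_distance(msa)

    def test_monotone_in_mismatch_fraction(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        dists = []
        for k in (1, 4, 8, 12):
            # mutate first k sites to residues different from the original
            other = "".join(
                ("W" if base[i] != "W" else "Y") if i < k else base[i]
                for i in range(len(base))
            )
            msa = MSA(ids=["a", "b"], rows=[base, other])
            D, _ = protein_distance(msa)
            dists.append(D[0, 1])
        assert all(x < y for x, y in zip(dists, dists[1:]))

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACDE"), size=30)) for _ in range(5)]
        msa = MSA(ids=[f"s{i}" for i in range(5)], rows=rows)
        D, _ = protein_distance(msa)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


class TestNeighborJoining:
    def test_recovers_known_additive_example(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives these pairwise path lengths
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(D, labels)
        D2 = tree_distance_matrix(tree, labels)
        assert np.allclose(D, D2, atol=1e-9)
        assert bipartitions(tree) == {frozenset({"A", "B"})}

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(D, labels)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_quartet_topology_matches_four_point_condition(self):
        rng = np.random.default_rng(8)
        from conftest import random_additive_tree

        for _ in range(25):
            true_tree, labels = random_additive_tree(4, rng)
            D = tree_distance_matrix(true_tree, labels)
            # four-point condition: the smallest of the three pairings wins
            s_ab_cd = D[0, 1] + D[2, 3]
            s_ac_bd = D[0, 2] + D[1, 3]
            s_ad_bc = D[0, 3] + D[1, 2]
            best = min(s_ab_cd, s_ac_bd, s_ad_bc)
            expected = {
                s_ab_cd: frozenset({labels[0], labels[1]}),
                s_ac_bd: frozenset({labels[0], labels[2]}),
                s_ad_bc: frozenset({labels[0], labels[3]}),
            }[best]
            nj = neighbor_joining(D, labels)
            split = next(iter(bipartitions(nj)))
            canon = split if labels[0] in split else frozenset(labels) - split
            assert canon == expected

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]), list("ABC"))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(np.zeros((2, 2)), list("AB"))


def _two_clade_msa(n_per_clade=3, n_cols=20):
    """Two internally identical clades differing at every column."""
    ids = [f"A{i}" for i in range(n_per_clade)] + [f"B{i}" for i in range(n_per_clade)]
    rows = ["A" * n_cols] * n_per_clade + ["C" * n_cols] * n_per_clade
    return MSA(ids=ids, rows=rows)


class TestBootstrap:
    def test_fixed_clades_supported_in_every_replicate(self):
        msa = _two_clade_msa(2)
        gt = bootstrap_support(msa, n_replicates=50, seed=1)
        assert set(gt.bootstrap.values()) == {50}

    def test_counts_bounded_and_deterministic(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("ACDEFG"), size=40)) for _ in range(6)]
        msa = MSA(ids=[f"s{i}" for i in range(6)], rows=rows)
        a = bootstrap_support(msa, n_replicates=30, seed=7)
        b = bootstrap_support(msa, n_replicates=30, seed=7)
        assert a.bootstrap == b.bootstrap
        assert all(0 <= v <= 30 for v in a.bootstrap.values())


class TestParsimony:
    def test_constant_column_costs_nothing(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        msa = MSA(ids=list("abcd"), rows=["A", "A", "A", "A"])
        assert parsimony_score(msa, tree) == 0

    def test_two_state_split_costs_one(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        msa = MSA(ids=list("abcd"), rows=["A", "A", "C", "C"])
        assert parsimony_score(msa, tree) == 1

    def test_gaps_are_missing_not_states(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        msa = MSA(ids=list("abcd"), rows=["A", "-", "C", "-"])
        assert parsimony_score(msa, tree) == 1

    def test_leaf_mismatch_rejected(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        msa = MSA(ids=list("abce"), rows=["A"] * 4)
        with pytest.raises(ValueError, match="leaves"):
            parsimony_score(msa, tree)


class TestSplitSubtypes:
    def test_two_leaves_one_per_subtype(self):
        tree = dendropy.Tree.get(data="(a:1,b:1);", schema="newick")
        labels = split_subtypes(tree)
        assert sorted(labels.values()) == ["I", "II"]

    def test_relabeling_leaves_permutes_assignment(self):
        nwk = "((a:1,b:1):2,(c:1,d:1,e:1):2);"
        tree1 = dendropy.Tree.get(data=nwk, schema="newick")
        labels1 = split_subtypes(tree1)
        swap = {"a": "c", "b": "d", "c": "a", "d": "b", "e": "e"}
        nwk2 = "((c:1,d:1):2,(a:1,b:1,e:1):2);"
        tree2 = dendropy.Tree.get(data=nwk2, schema="newick")
        labels2 = split_subtypes(tree2)
        assert labels2 == {swap[k]: v for k, v in labels1.items()}

    def test_zero_length_tree_unassigned(self):
        tree = dendropy.Tree.get(data="(a:0,b:0,c:0);", schema="newick")
        with pytest.warns(UserWarning, match="zero total length"):
            labels = split_subtypes(tree)
        assert set(labels.values()) == {"unassigned"}

    def test_reference_leaf_pins_subtype_one(self):
        nwk = "((a:1,b:1):2,(c:1,d:1,e:1):2);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        labels = split_subtypes(tree, reference_leaf="a")
        assert labels["a"] == "I" and labels["c"] == "II"
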