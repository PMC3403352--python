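"""Local alignment, E-values, family search and BBH orthology."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitscan.genome_io import Gene, Genome
from traitscan.homology import (
    bidirectional_best_hits,
    evalue,
    find_family_members,
    search_genomes,
    smith_waterman,
)

short_protein = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12)


class TestSmithWaterman:
    def test_identity_score_is_blosum_diagonal_sum(self):
        # A4 + C9 + D6 + E5 + F6 + G6 under BLOSUM62
        hit = smith_waterman("ACDEFG", "ACDEFG")
        assert hit.raw_score == 36
        assert (hit.q_start, hit.q_end, hit.s_start, hit.s_end) == (0, 6, 0, 6)

    def test_no_positive_pair_gives_empty_alignment(self):
        hit = smith_waterman("AAAA", "WWWW")
        assert hit.raw_score == 0
        assert (hit.q_start, hit.q_end, hit.s_start, hit.s_end) == (0, 0, 0, 0)

    @given(short_protein, short_protein)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_score_is_symmetric(self, a, b):
        assert smith_waterman(a, b).raw_score == smith_waterman(b, a).raw_score

    @given(short_protein, short_protein)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_self_score_dominates(self, a, b):
        assert smith_waterman(a, a).raw_score >= smith_waterman(a, b).raw_score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACD")

    def test_gap_costs_open_plus_extend(self):
        # CCECC vs CCCC: bridging E with a length-1 gap costs 11 + 1, giving
        # 4*C(9) - 12 = 24, better than the E/C mismatch path (27 - 4 = 23)
        hit = smith_waterman("CCECC", "CCCC")
        assert hit.raw_score == 4 * 9 - 12


class TestEvalue:
    def test_reference_point(self):
        assert evalue(36, 200, 200) == pytest.approx(0.0572, abs=2e-4)

    def test_monotone_decreasing_in_score(self):
        es = [evalue(s, 100, 100) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert evalue(10000, 100, 100) < 1e-300

    def test_linear_in_length(self):
        assert evalue(30, 400, 100) == pytest.approx(2 * evalue(30, 200, 100))

    @pytest.mark.parametrize("kwargs", [{"len_a": 0}, {"lambda_": 0}, {"K": -1}])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(raw_score=10, len_a=100, len_b=100)
        base.update(kwargs)
        with pytest.raises(ValueError):
            evalue(**base)


def _genome(genome_id, seqs):
    contig = []
    pos = 0
    for i, (gid, seq) in enumerate(seqs):
        contig.append(Gene(gid, "c1", pos, pos + 3 * len(seq), "+", seq))
        pos += 3 * len(seq) + 200
    g = Genome(genome_id=genome_id)
    g.contigs["c1"] = contig
    return g


SEED_A = "MKVLAADTCHEWGRKLYNNPQSTFYAMKVLAADTCHEWGR"
SEED_B = "WWCCHHKKPPRRSSTTGGLLMMNNQQEEDDFFYYVVIIAA"


class TestFamilySearch:
    def test_identical_gene_retained_and_unrelated_excluded(self):
        genome = _genome("G1", [("G1_a", SEED_A), ("G1_x", "MP")])
        seeds = {"famA": {"famA_seed": SEED_A}}
        table = find_family_members([genome], seeds)
        assert "G1_a" in set(table.subject_id)
        # a 2-residue unrelated gene cannot reach E <= 0.1
        assert "G1_x" not in set(table.subject_id)

    def test_cutoff_excludes_weak_hits(self):
        genome = _genome("G1", [("G1_x", SEED_B)])
        seeds = {"famA": {"famA_seed": SEED_A}}
        table = find_family_members([genome], seeds, evalue_cutoff=0.1)
        strong = table[table.evalue <= 0.1]
        weak_only = find_family_members([genome], seeds, evalue_cutoff=1e9)
        assert (table.evalue <= 0.1).all()
        assert len(weak_only) >= len(strong)

    def test_orthologs_recovered_by_reciprocal_best_hits(self, small_sim):
        _, omap = search_genomes(
            small_sim.genomes, small_sim.seeds, with_spans=False
        )
        truth = small_sim.truth["presence"]
        correct = total = 0
        for fam, by_genome in truth.items():
            for gid, present in by_genome.items():
                if present:
                    total += 1
                    correct += omap.gene_for(fam, gid) == f"{gid}_{fam}"
        assert total > 0
        assert correct / total >= 0.99

    def test_ortholog_map_is_partial_matching(self, small_sim):
        _, omap = search_genomes(small_sim.genomes, small_sim.seeds, with_spans=False)
        for genome in small_sim.genomes:
            used = [
                omap.assignments[fam][genome.genome_id]
                for fam in omap.families
                if genome.genome_id in omap.assignments[fam]
            ]
            assert len(used) == len(set(used))


class TestBidirectionalBestHits:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows, columns=["query_id", "subject_id", "raw_score", "evalue"]
        )

    def test_reciprocal_pairs_reported(self):
        ab = self._table([("x1", "y1", 100, 1e-30), ("x1", "y2", 50, 1e-10)])
        ba = self._table([("y1", "x1", 100, 1e-30), ("y2", "x2", 60, 1e-12)])
        assert bidirectional_best_hits(ab, ba) == [("x1", "y1")]

    def test_non_reciprocal_best_excluded(self):
        ab = self._table([("x", "y", 80, 1e-20)])
        ba = self._table([("y", "z", 90, 1e-25), ("y", "x", 80, 1e-20)])
        assert bidirectional_best_hits(ab, ba) == []

    def test_score_tie_broken_by_evalue_then_id(self):
        ab = self._table(
            [("x", "y2", 70, 1e-15), ("x", "y1", 70, 1e-15)]
        )
        ba = self._table([("y1", "x", 70, 1e-15), ("y2", "x", 70, 1e-15)])
        # identical score and E: lexicographically smaller subject wins
        assert bidirectional_best_hits(ab, ba) == [("x", "y1")]

    def test_output_is_partial_matching(self):
        rng = np.random.default_rng(0)
        rows_ab, rows_ba = [], []
        for i in range(6):
            for j in range(6):
                s = int(rng.integers(10, 90))
                rows_ab.append((f"x{i}", f"y{j}", s, math.exp(-s)))
                rows_ba.append((f"y{j}", f"x{i}", s, math.exp(-s)))
        pairs = bidirectional_best_hits(self._table(rows_ab), self._table(rows_ba))
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        assert len(xs) == len(set(xs)) and len(ys) == len(set(ys))
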