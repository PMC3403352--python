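"""Phyletic profiles, trait signature, co-occurrence and partner ranking."""

import numpy as np
import pandas as pd
import pytest

from traitscan.homology import OrthologMap
from traitscan.profiles import (
    PhyleticProfile,
    build_profile,
    call_trait,
    cooccurrence,
    detect_fusions,
    mutual_information_2x2,
    occurrence_by_taxon,
    rank_partners,
)
from traitscan.genome_io import Gene, Genome


def _profile(matrix, genomes=None, families=None):
    matrix = np.asarray(matrix)
    genomes = genomes or [f"G{i}" for i in range(matrix.shape[0])]
    families = families or [f"f{j}" for j in range(matrix.shape[1])]
    return PhyleticProfile(matrix=pd.DataFrame(matrix, index=genomes, columns=families))


class TestBuildProfile:
    def test_cells_follow_ortholog_assignments(self):
        omap = OrthologMap(families=["ruvA", "ruvB", "ruvC"])
        omap.assignments = {
            "ruvA": {"G1": "G1_a"},
            "ruvB": {"G1": "G1_b"},
            "ruvC": {"G1": "G1_c"},
        }
        genomes = [Genome(genome_id="G1"), Genome(genome_id="G2")]
        profile = build_profile(omap, genomes)
        assert profile.matrix.loc["G1"].tolist() == [1, 1, 1]
        assert profile.matrix.loc["G2"].tolist() == [0, 0, 0]  # empty genome
        assert profile.provenance.loc["G1", "ruvA"] == "G1_a"


class TestTraitCall:
    @pytest.mark.parametrize(
        "row,status",
        [
            ((1, 1, 1, 0), "RuvABC"),
            ((1, 1, 0, 1), "RuvAB+RecU"),
            ((1, 1, 1, 1), "both"),
            ((1, 1, 0, 0), "RuvAB-only"),
            ((0, 0, 0, 0), "absent"),
            ((1, 0, 1, 0), "absent"),
        ],
    )
    def test_signature_rules(self, row, status):
        series = pd.Series(dict(zip(("ruvA", "ruvB", "ruvC", "recU"), row)))
        assert call_trait(series, "G").status == status

    def test_ruvc_without_ruvab_flags_anomaly(self):
        series = pd.Series({"ruvA": 0, "ruvB": 1, "ruvC": 1, "recU": 0})
        call = call_trait(series, "G")
        assert call.status == "absent"
        assert call.anomalies == ["ruvC-without-ruvAB"]


class TestCooccurrence:
    def test_identical_profiles_single_admissible_table(self):
        x = [1] * 5 + [0] * 5
        profile = _profile(np.column_stack([x, x]), families=["a", "b"])
        out = cooccurrence(profile, "a", "b")
        assert out["jaccard"] == 1.0
        assert out["fisher_p"] == pytest.approx(1 / 252, rel=1e-9)

    def test_complement_profiles_share_nothing(self):
        x = np.array([1, 1, 1, 0, 0, 0])
        profile = _profile(np.column_stack([x, 1 - x]), families=["a", "b"])
        assert cooccurrence(profile, "a", "b")["jaccard"] == 0.0

    def test_symmetry_and_self_identities(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, size=(20, 2))
        m[0] = [1, 1]  # avoid the all-absent edge case
        profile = _profile(m, families=["a", "b"])
        ab = cooccurrence(profile, "a", "b")
        ba = cooccurrence(profile, "b", "a")
        assert ab["jaccard"] == ba["jaccard"]
        assert ab["fisher_p"] == pytest.approx(ba["fisher_p"])
        aa = cooccurrence(profile, "a", "a")
        assert aa["jaccard"] == 1.0
        # MI of a variable with itself is its entropy
        p = profile.matrix["a"].mean()
        entropy = -p * np.log(p) - (1 - p) * np.log(1 - p)
        assert aa["mutual_information"] == pytest.approx(entropy)

    def test_absent_family_yields_nulls_with_warning(self):
        profile = _profile([[1, 0], [1, 0], [0, 0]], families=["a", "b"])
        with pytest.warns(UserWarning, match="absent everywhere"):
            out = cooccurrence(profile, "a", "b")
        assert out == {"jaccard": 0.0, "mutual_information": 0.0, "fisher_p": 1.0}

    def test_mi_of_independent_margins_is_zero(self):
        table = np.array([[4, 4], [4, 4]])
        assert mutual_information_2x2(table) == pytest.approx(0.0, abs=1e-12)


class TestRankPartners:
    def test_anchor_families_excluded_from_ranking(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(15, 5))
        profile = _profile(m, families=["ruvA", "ruvB", "d1", "d2", "d3"])
        report = rank_partners(profile, ["ruvA", "ruvB"])
        assert set(report.family) == {"d1", "d2", "d3"}

    def test_relabeling_decoys_permutes_ranks_identically(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 2, size=(20, 4))
        anchor = rng.integers(0, 2, size=20)
        fams = ["d1", "d2", "d3", "d4"]
        profile = _profile(m, families=fams)
        rep1 = rank_partners(profile, [], anchor_vector=anchor)
        renamed = {"d1": "z9", "d2": "z8", "d3": "z7", "d4": "z6"}
        profile2 = _profile(m, families=[renamed[f] for f in fams])
        rep2 = rank_partners(profile2, [], anchor_vector=anchor)
        merged = rep1.assign(family=rep1.family.map(renamed)).merge(
            rep2, on="family", suffixes=("_1", "_2")
        )
        assert (merged.combined_1 == merged.combined_2).all()

    def test_missing_anchor_family_rejected(self):
        profile = _profile([[1], [0]], families=["d1"])
        with pytest.raises(ValueError, match="anchor"):
            rank_partners(profile, ["ruvA"])

    def test_combined_score_noisy_or(self):
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        profile = _profile(x[:, None], families=["d1"])
        report = rank_partners(
            profile, [], neighborhood_scores={"d1": 0.5}, anchor_vector=x
        )
        s_cooc = report.s_cooc.iloc[0]
        assert report.combined.iloc[0] == pytest.approx(1 - (1 - s_cooc) * 0.5)


class TestFusions:
    @staticmethod
    def _hits(rows):
        cols = [
            "query_id",
            "family",
            "subject_id",
            "genome_id",
            "raw_score",
            "evalue",
            "q_start",
            "q_end",
            "s_start",
            "s_end",
        ]
        return pd.DataFrame(rows, columns=cols)

    SEEDS = {"famA": {"sa": "A" * 100}, "famB": {"sb": "C" * 100}}

    def test_disjoint_spans_with_coverage_detected(self):
        hits = self._hits(
            [
                ("sa", "famA", "g1", "G1", 300, 1e-30, 0, 80, 0, 80),
                ("sb", "famB", "g1", "G1", 300, 1e-30, 0, 80, 100, 180),
            ]
        )
        assert detect_fusions(hits, self.SEEDS) == {("famA", "famB")}

    def test_overlapping_spans_not_fusion(self):
        hits = self._hits(
            [
                ("sa", "famA", "g1", "G1", 300, 1e-30, 0, 80, 0, 80),
                ("sb", "famB", "g1", "G1", 300, 1e-30, 0, 80, 40, 120),
            ]
        )
        assert detect_fusions(hits, self.SEEDS) == set()

    def test_low_coverage_not_fusion(self):
        hits = self._hits(
            [
                ("sa", "famA", "g1", "G1", 100, 1e-10, 0, 30, 0, 30),
                ("sb", "famB", "g1", "G1", 300, 1e-30, 0, 80, 100, 180),
            ]
        )
        assert detect_fusions(hits, self.SEEDS) == set()


class TestOccurrenceByTaxon:
    @staticmethod
    def _genomes(labels):
        out = []
        for gid, taxon in labels.items():
            g = Genome(genome_id=gid, taxon_label=taxon)
            out.append(g)
        return out

    def test_fraction_with_trait(self):
        m = pd.DataFrame(
            {
                "ruvA": [1, 1, 1, 0],
                "ruvB": [1, 1, 1, 0],
                "ruvC": [1, 1, 1, 0],
                "recU": [0, 0, 0, 0],
            },
            index=["G1", "G2", "G3", "G4"],
        )
        profile = PhyleticProfile(matrix=m)
        genomes = self._genomes({g: "phy1" for g in m.index})
        table = occurrence_by_taxon(profile, genomes)
        row = table[table.taxon == "phy1"].iloc[0]
        assert row.n_genomes == 4
        assert row["frac_RuvABC"] == 0.75

    def test_status_fractions_partition_each_taxon(self, small_sim):
        from traitscan.pipeline import compute_linkage

        profile, _, _, _ = compute_linkage(small_sim.genomes, small_sim.seeds)
        table = occurrence_by_taxon(profile, small_sim.genomes)
        statuses = ["RuvABC", "RuvAB+RecU", "both", "RuvAB-only", "absent"]
        sums = table[[f"frac_{s}" for s in statuses]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_unresolvable_label_goes_to_unmapped(self):
        import dendropy

        m = pd.DataFrame({"ruvA": [1, 0]}, index=["G1", "G2"])
        profile = PhyleticProfile(matrix=m)
        genomes = self._genomes({"G1": "phyX", "G2": "weird"})
        tree = dendropy.Tree.get(data="(phyX,phyY);", schema="newick")
        with pytest.warns(UserWarning, match="unmapped"):
            table = occurrence_by_taxon(profile, genomes, reference_tree=tree)
        assert set(table.taxon) == {"phyX", "unmapped"}
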