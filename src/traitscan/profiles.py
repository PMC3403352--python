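"""Phyletic profiles, trait signatures, co-occurrence and partner ranking.

The Holliday-junction resolution trait is called from gene presence alone:
RuvAB plus either RuvC or RecU is the signature of a working
resolvasome, RuvAB without either resolvase is flagged separately, and RuvC
without RuvAB is anomalous. Candidate partner families of the anchor set are
ranked by combining a co-occurrence channel (Fisher exact enrichment on the
2x2 presence table) with a gene-neighborhood channel and an optional
gene-fusion bonus: combined = 1 - (1 - s_cooc) * (1 - s_nbr) * (1 - s_fus).

Profiles are treated as i.i.d. across genomes; no phylogenetic correction
is applied to the co-occurrence statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_FAMILIES = ("ruvA", "ruvB", "ruvC", "recU")

#: statuses carrying a complete resolution system
RESOLVING_STATUSES = frozenset({"RuvABC", "RuvAB+RecU", "both"})

FUSION_BONUS = 0.5


@dataclass
class PhyleticProfile:
    """Binary genomes x families matrix with per-cell provenance."""

    matrix: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        values = self.matrix.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("profile entries must be 0/1")
        if self.matrix.index.has_duplicates or self.matrix.columns.has_duplicates:
            raise ValueError("genome and family labels must be unique")

    @property
    def genomes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def families(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class TraitCall:
    genome_id: str
    status: str
    anomalies: list[str] = field(default_factory=list)


def build_profile(ortholog_map, genomes) -> PhyleticProfile:
    """Presence/absence matrix from BBH ortholog calls.

    Cell (g, f) is 1 iff an ortholog of family f was assigned in genome g;
    provenance records the supporting gene ID.
    """
    genome_ids = [g.genome_id for g in genomes]
    families = list(ortholog_map.families)
    matrix = pd.DataFrame(0, index=genome_ids, columns=families, dtype=int)
    prov = pd.DataFrame("", index=genome_ids, columns=families, dtype=object)
    for fam in families:
        for genome_id, gene_id in ortholog_map.assignments.get(fam, {}).items():
            if genome_id in matrix.index:
                matrix.loc[genome_id, fam] = 1
                prov.loc[genome_id, fam] = gene_id
    return PhyleticProfile(matrix=matrix, provenance=prov)


def call_trait(profile_row: pd.Series, genome_id: str = "") -> TraitCall:
    """Resolution-trait status from one profile row.

    RuvABC if A&B&C&~U; RuvAB+RecU if A&B&U&~C; both if A&B&C&U;
    RuvAB-only if A&B&~C&~U; absent otherwise. RuvC present without
    RuvAB raises an anomaly flag (every RuvC genome is expected to carry
    RuvA and RuvB).
    """
    a = bool(profile_row.get("ruvA", 0))
    b = bool(profile_row.get("ruvB", 0))
    c = bool(profile_row.get("ruvC", 0))
    u = bool(profile_row.get("recU", 0))
    gid = genome_id or str(profile_row.name)
    if a and b:
        if c and u:
            status = "both"
        elif c:
            status = "RuvABC"
        elif u:
            status = "RuvAB+RecU"
        else:
            status = "RuvAB-only"
    else:
        status = "absent"
    anomalies = []
    if c and not (a and b):
        anomalies.append("ruvC-without-ruvAB")
    return TraitCall(genome_id=gid, status=status, anomalies=anomalies)


def call_traits(profile: PhyleticProfile) -> pd.DataFrame:
    rows = []
    for gid in profile.genomes:
        call = call_trait(profile.matrix.loc[gid], gid)
        rows.append((gid, call.status, ";".join(call.anomalies)))
    return pd.DataFrame(rows, columns=["genome_id", "status", "anomalies"]).set_index(
        "genome_id"
    )


def _table2x2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return np.array([[n11, n10], [n01, n00]])


def mutual_information_2x2(table: np.ndarray) -> float:
    """MI (nats) of the empirical 2x2 joint distribution."""
    n = table.sum()
    if n == 0:
        return 0.0
    p = table / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if p[i, j] > 0:
                mi += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return max(mi, 0.0)


def cooccurrence(profile: PhyleticProfile, family_x: str, family_y: str) -> dict:
    """Jaccard, mutual information and one-tailed Fisher enrichment p.

    A family absent from every genome yields jaccard = MI = 0 and p = 1
    with a warning (no signal, not an error).
    """
    if len(profile.genomes) < 2:
        raise ValueError("co-occurrence needs at least 2 genomes")
    x = profile.matrix[family_x].to_numpy()
    y = profile.matrix[family_y].to_numpy()
    if x.sum() == 0 or y.sum() == 0:
        warnings.warn(
            f"family {'/'.join(f for f, v in ((family_x, x), (family_y, y)) if v.sum() == 0)} "
            "absent everywhere; co-occurrence undefined, returning null values"
        )
        return {"jaccard": 0.0, "mutual_information": 0.0, "fisher_p": 1.0}
    union = int(np.sum((x == 1) | (y == 1)))
    inter = int(np.sum((x == 1) & (y == 1)))
    jaccard = inter / union if union else 0.0
    table = _table2x2(x, y)
    _, fisher_p = stats.fisher_exact(table, alternative="greater")
    return {
        "jaccard": jaccard,
        "mutual_information": mutual_information_2x2(table),
        "fisher_p": float(fisher_p),
    }


def detect_fusions(hit_table: pd.DataFrame, seeds: dict[str, dict[str, str]], min_coverage: float = 0.6) -> set[tuple[str, str]]:
    """Gene-fusion evidence between family pairs.

    A gene counts as a fusion of families F1 and F2 if its hits cover at
    least ``min_coverage`` of a seed from each family on disjoint gene
    (subject) spans. Returns unordered family pairs with evidence.
    """
    seed_len = {
        seed_id: len(seq)
        for fam in seeds
        for seed_id, seq in seeds[fam].items()
    }
    out: set[tuple[str, str]] = set()
    if hit_table.empty:
        return out
    for _, grp in hit_table.groupby("subject_id"):
        strong = grp[
            (grp.q_end - grp.q_start) / grp.query_id.map(seed_len) >= min_coverage
        ]
        fams = strong.groupby("family")
        if len(fams) < 2:
            continue
        recs = [grp_f.iloc[0] for _, grp_f in fams]
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if a.s_end <= b.s_start or b.s_end <= a.s_start:
                    out.add(tuple(sorted((a.family, b.family))))
    return out


def rank_partners(
    profile: PhyleticProfile,
    anchor_families: list[str],
    neighborhood_scores: dict[str, float] | None = None,
    fusion_pairs: set[tuple[str, str]] | None = None,
    anchor_vector: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank non-anchor families by combined linkage evidence.

    ``anchor_vector`` is the per-genome presence of the anchor system; by
    default the AND of the anchor-family columns (the pipeline passes the
    trait-signature vector instead, so genomes using RecU as resolvase still
    count). Channels map to [0, 1): s_cooc = 1 - fisher_p, s_nbr from the
    neighborhood module, s_fus a fixed bonus when a fusion with any anchor
    exists. combined = 1 - (1-s_cooc)(1-s_nbr)(1-s_fus).
    """
    missing = [f for f in anchor_families if f not in profile.families]
    if missing:
        raise ValueError(f"anchor families not in profile: {missing}")
    if anchor_vector is None:
        anchor_vector = np.ones(len(profile.genomes), dtype=int)
        for fam in anchor_families:
            anchor_vector &= profile.matrix[fam].to_numpy()
    anchor_vector = np.asarray(anchor_vector, dtype=int)
    neighborhood_scores = neighborhood_scores or {}
    fusion_pairs = fusion_pairs or set()
    anchor_set = set(anchor_families)
    rows = []
    for fam in profile.families:
        if fam in anchor_set:
            continue
        y = profile.matrix[fam].to_numpy()
        if anchor_vector.sum() == 0 or y.sum() == 0:
            fisher_p = 1.0
        else:
            table = _table2x2(anchor_vector, y)
            _, fisher_p = stats.fisher_exact(table, alternative="greater")
        s_cooc = min(1.0 - float(fisher_p), 1.0 - 1e-12)
        s_nbr = float(neighborhood_scores.get(fam, 0.0))
        fused = any(tuple(sorted((fam, a))) in fusion_pairs for a in anchor_families)
        s_fus = FUSION_BONUS if fused else 0.0
        combined = 1.0 - (1.0 - s_cooc) * (1.0 - s_nbr) * (1.0 - s_fus)
        rows.append((fam, s_cooc, s_nbr, int(fused), combined))
    report = pd.DataFrame(
        rows, columns=["family", "s_cooc", "s_nbr", "fusion", "combined"]
    )
    report = report.sort_values(
        ["combined", "family"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report


def occurrence_by_taxon(
    profile: PhyleticProfile,
    genomes,
    reference_tree=None,
) -> pd.DataFrame:
    """Per-taxon occurrence fractions of each family and trait status.

    Genomes whose taxon label cannot be resolved to a leaf or named clade of
    the reference tree are grouped under "unmapped" with a warning. Trait
    statuses partition each taxon, so their fractions sum to 1.
    """
    taxon_of = {g.genome_id: (g.taxon_label or "unlabeled") for g in genomes}
    if reference_tree is not None:
        known = {lf.taxon.label for lf in reference_tree.leaf_node_iter()}
        known |= {
            nd.label for nd in reference_tree.preorder_node_iter() if nd.label
        }
        unmapped = sorted({t for t in taxon_of.values() if t not in known})
        if unmapped:
            warnings.warn(f"unresolvable taxon labels mapped to 'unmapped': {unmapped}")
            taxon_of = {
                g: (t if t in known else "unmapped") for g, t in taxon_of.items()
            }
    calls = call_traits(profile)
    rows = []
    statuses = ["RuvABC", "RuvAB+RecU", "both", "RuvAB-only", "absent"]
    for taxon in sorted(set(taxon_of.values())):
        members = [g for g in profile.genomes if taxon_of.get(g) == taxon]
        if not members:
            continue
        n = len(members)
        row: dict = {"taxon": taxon, "n_genomes": n}
        sub = profile.matrix.loc[members]
        for fam in profile.families:
            row[f"frac_{fam}"] = float(sub[fam].mean())
        for status in statuses:
            row[f"frac_{status}"] = float(
                (calls.loc[members, "status"] == status).mean()
            )
        rows.append(row)
    return pd.DataFrame(rows)
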