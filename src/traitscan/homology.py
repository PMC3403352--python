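"""Homolog detection and bidirectional-best-hit (BBH) orthology.

Family members are found by optimal local alignment (affine-gap
Smith-Waterman, BLOSUM62 by default) of every gene against a set of seed
sequences, filtered at a permissive E-value cutoff (0.1) computed from the
ungapped Karlin-Altschul formula E = K*m*n*exp(-lambda*S). Orthology is then
assigned per family by reciprocal best hits between a genome's proteome and
the seed set: the seed's best gene must name the seed's family as its own
best seed (the "seed-set vote"). Extra members above the cutoff are reported
as paralogs, never as orthologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from ._aligncore import sw_fill, sw_score

DEFAULT_LAMBDA = 0.318
DEFAULT_K = 0.134
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

HIT_COLUMNS = [
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


@lru_cache(maxsize=4)
def load_matrix(name: str = "blosum62"):
    """Return (score array, char->index map) for a named substitution matrix."""
    mat = substitution_matrices.load(name.upper())
    S = np.asarray(mat, dtype=np.float64)
    index = {ch: i for i, ch in enumerate(mat.alphabet)}
    return S, index


def encode(seq: str, index: dict[str, int]) -> np.ndarray:
    try:
        return np.array([index[ch] for ch in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"letter {exc} not in substitution-matrix alphabet") from exc


@dataclass
class AlignmentHit:
    """One local alignment; spans are 0-based half-open on both sequences."""

    query_id: str
    subject_id: str
    raw_score: float
    evalue: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("local alignment score cannot be negative")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")


def evalue(
    raw_score: float,
    len_a: int,
    len_b: int,
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if lambda_ <= 0 or K <= 0:
        raise ValueError("lambda_ and K must be positive")
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    return K * len_a * len_b * math.exp(-lambda_ * raw_score)


def _sw_traceback_spans(H, E, F, a, b, S, gap_open, gap_extend):
    """Spans of the optimal local alignment under the deterministic tie
    rules: best cell = highest score at lowest row then column; moves prefer
    diagonal > up > left; within a gap, closing (returning to H) is
    preferred."""
    flat = int(np.argmax(H))  # row-major argmax = lowest row, then column
    i, j = divmod(flat, H.shape[1])
    if H[i, j] <= 0:
        return 0.0, (0, 0, 0, 0)
    score = float(H[i, j])
    end_i, end_j = i, j
    eps = 1e-9
    state = "H"
    while True:
        if state == "H":
            if H[i, j] <= eps:
                break
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[a[i - 1], b[j - 1]])) < eps:
                i -= 1
                j -= 1
            elif i > 0 and abs(H[i, j] - E[i, j]) < eps:
                state = "E"
            elif j > 0 and abs(H[i, j] - F[i, j]) < eps:
                state = "F"
            else:  # pragma: no cover
                raise RuntimeError("inconsistent local traceback")
        elif state == "E":
            opened = abs(E[i, j] - (H[i - 1, j] - gap_open - gap_extend)) < eps
            i -= 1
            state = "H" if opened else "E"
        else:
            opened = abs(F[i, j] - (H[i, j - 1] - gap_open - gap_extend)) < eps
            j -= 1
            state = "H" if opened else "F"
    return score, (i, end_i, j, end_j)


def smith_waterman(
    seq_a: str,
    seq_b: str,
    matrix: str = "blosum62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> AlignmentHit:
    """Optimal affine-gap local alignment of two protein sequences.

    A gap of length k costs ``gap_open + k * gap_extend``. An all-negative
    score matrix yields score 0 with an empty alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if not gap_open >= gap_extend >= 0:
        raise ValueError("require gap_open >= gap_extend >= 0")
    S, index = load_matrix(matrix)
    a = encode(seq_a, index)
    b = encode(seq_b, index)
    H, E, F = sw_fill(a, b, S, gap_open, gap_extend)
    score, (qs, qe, ss, se) = _sw_traceback_spans(H, E, F, a, b, S, gap_open, gap_extend)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        evalue=evalue(score, len(seq_a), len(seq_b), lambda_, K),
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
    )


@dataclass
class OrthologMap:
    """Per-family, per-genome ortholog calls backed by reciprocal hits."""

    families: list[str]
    assignments: dict[str, dict[str, str]] = field(default_factory=dict)
    paralogs: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    support: dict[tuple[str, str], dict] = field(default_factory=dict)

    def gene_for(self, family: str, genome_id: str) -> str | None:
        return self.assignments.get(family, {}).get(genome_id)


def _seed_list(seeds: dict[str, dict[str, str]]):
    """Flatten {family: {seed_id: seq}} into parallel ordered lists."""
    seed_ids, seed_fams, seed_seqs = [], [], []
    for family in sorted(seeds):
        for seed_id in sorted(seeds[family]):
            seed_ids.append(seed_id)
            seed_fams.append(family)
            seed_seqs.append(seeds[family][seed_id])
    if not seed_ids:
        raise ValueError("at least one seed sequence is required")
    return seed_ids, seed_fams, seed_seqs


def _score_genome(genes, seed_codes, S, gap_open, gap_extend, index):
    """raw-score matrix genes x seeds."""
    scores = np.zeros((len(genes), len(seed_codes)))
    gene_codes = [encode(g.protein_seq, index) for g in genes]
    for gi, gc in enumerate(gene_codes):
        for si, sc in enumerate(seed_codes):
            scores[gi, si] = sw_score(sc, gc, S, gap_open, gap_extend)
    return scores, gene_codes


def search_genomes(
    genomes,
    seeds: dict[str, dict[str, str]],
    evalue_cutoff: float = 0.1,
    matrix: str = "blosum62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
    with_spans: bool = True,
) -> tuple[pd.DataFrame, OrthologMap]:
    """Full search + orthology pass over a genome collection.

    Returns the hit table (all seed-gene pairs with E <= cutoff, scores and
    spans retained) and the BBH ortholog map. Ortholog call for family F in
    genome g: gene x such that x is seed s's best gene in g and s (of family
    F) is x's best seed overall, ties broken by raw score, then E-value,
    then lexicographic ID; a tie surviving all breaks disqualifies the pair.
    """
    S, index = load_matrix(matrix)
    seed_ids, seed_fams, seed_seqs = _seed_list(seeds)
    seed_codes = [encode(s, index) for s in seed_seqs]
    families = sorted(seeds)
    omap = OrthologMap(families=families)
    for fam in families:
        omap.assignments[fam] = {}
        omap.paralogs[fam] = {}
    rows = []
    for genome in genomes:
        genes = genome.genes()
        if not genes:
            continue
        scores, gene_codes = _score_genome(genes, seed_codes, S, gap_open, gap_extend, index)
        evals = np.empty_like(scores)
        for si, sseq in enumerate(seed_seqs):
            for gi, gene in enumerate(genes):
                evals[gi, si] = evalue(
                    scores[gi, si], len(sseq), len(gene.protein_seq), lambda_, K
                )
        # hit table: every passing (seed, gene) pair
        for gi, gene in enumerate(genes):
            for si in np.flatnonzero(evals[gi] <= evalue_cutoff):
                si = int(si)
                if with_spans:
                    Hm, Em, Fm = sw_fill(seed_codes[si], gene_codes[gi], S, gap_open, gap_extend)
                    _, (qs, qe, ss, se) = _sw_traceback_spans(
                        Hm, Em, Fm, seed_codes[si], gene_codes[gi], S, gap_open, gap_extend
                    )
                else:
                    qs = qe = ss = se = 0
                rows.append(
                    (
                        seed_ids[si],
                        seed_fams[si],
                        gene.gene_id,
                        genome.genome_id,
                        scores[gi, si],
                        evals[gi, si],
                        qs,
                        qe,
                        ss,
                        se,
                    )
                )
        # BBH between the genome's proteome and the seed set
        best_seed = _best_index(scores, evals, seed_ids)
        best_gene = _best_index(scores.T, evals.T, [g.gene_id for g in genes])
        candidates: dict[str, list[str]] = {fam: [] for fam in families}
        reciprocal: dict[str, list[tuple]] = {fam: [] for fam in families}
        for gi, gene in enumerate(genes):
            si = best_seed[gi]
            if si is None or evals[gi, si] > evalue_cutoff:
                continue
            fam = seed_fams[si]
            candidates[fam].append(gene.gene_id)
            if best_gene[si] == gi:
                reciprocal[fam].append(
                    (-scores[gi, si], evals[gi, si], gene.gene_id, seed_ids[si])
                )
        for fam in families:
            called = None
            if reciprocal[fam]:
                neg_score, ev, gene_id, seed_id = sorted(reciprocal[fam])[0]
                called = gene_id
                omap.assignments[fam][genome.genome_id] = gene_id
                omap.support[(fam, genome.genome_id)] = {
                    "gene_id": gene_id,
                    "seed_id": seed_id,
                    "raw_score": float(-neg_score),
                    "evalue": float(ev),
                }
            extras = sorted(g for g in candidates[fam] if g != called)
            if extras:
                omap.paralogs[fam][genome.genome_id] = extras
    table = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return table, omap


def _best_index(scores, evals, ids):
    """Per-row index of the best column: max score, then min E-value, then
    lexicographically smallest ID; identical duplicates disqualify (None)."""
    out = []
    for r in range(scores.shape[0]):
        order = sorted(
            range(scores.shape[1]),
            key=lambda c: (-scores[r, c], evals[r, c], ids[c]),
        )
        top = order[0]
        if len(order) > 1:
            nxt = order[1]
            if (
                scores[r, top] == scores[r, nxt]
                and evals[r, top] == evals[r, nxt]
                and ids[top] == ids[nxt]
            ):
                out.append(None)
                continue
        out.append(top)
    return out


def find_family_members(genomes, seeds, evalue_cutoff: float = 0.1, **kwargs) -> pd.DataFrame:
    """Candidate hit table: genes whose best seed passes E <= cutoff."""
    table, _ = search_genomes(genomes, seeds, evalue_cutoff, **kwargs)
    return table


def assign_orthologs(genomes, seeds, evalue_cutoff: float = 0.1, **kwargs) -> OrthologMap:
    """BBH ortholog map (one ortholog per family per genome at most)."""
    _, omap = search_genomes(genomes, seeds, evalue_cutoff, with_spans=False, **kwargs)
    return omap


def bidirectional_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> list[tuple[str, str]]:
    """Reciprocal best pairs from two directed hit tables.

    Each table needs columns query_id, subject_id, raw_score, evalue. (x, y)
    is reported iff y is x's unique best hit in B and x is y's unique best
    hit in A, with ties broken by raw score, then E-value, then
    lexicographic subject ID; a tie surviving all breaks disqualifies.
    """

    def best_map(df: pd.DataFrame) -> dict[str, str]:
        out: dict[str, str] = {}
        for query, grp in df.groupby("query_id"):
            grp = grp.sort_values(
                ["raw_score", "evalue", "subject_id"], ascending=[False, True, True]
            )
            top = grp.iloc[0]
            if len(grp) > 1:
                nxt = grp.iloc[1]
                if (
                    top.raw_score == nxt.raw_score
                    and top.evalue == nxt.evalue
                    and top.subject_id == nxt.subject_id
                ):
                    continue  # unresolvable tie disqualifies the query
            out[str(query)] = str(top.subject_id)
        return out

    fwd = best_map(hits_ab)
    rev = best_map(hits_ba)
    pairs = [(x, y) for x, y in fwd.items() if rev.get(y) == x]
    return sorted(pairs)
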