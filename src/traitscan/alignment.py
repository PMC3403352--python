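"""Progressive multiple sequence alignment and column masking.

A standard guide-tree progressive aligner: k-mer distances between the
input sequences, a UPGMA (average-linkage) guide tree, and profile-profile
Needleman-Wunsch merges under affine gaps. The column score between two
profiles is the expected substitution score over their residue frequencies
(gap frequencies score zero). Deterministic throughout: scipy's linkage
order fixes the merge order and the global traceback prefers
diagonal > up > left on ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._aligncore import nw_fill, nw_traceback
from .homology import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, load_matrix

GAP = "-"


@dataclass
class MSA:
    """Ordered aligned rows; ungapping row i reproduces input sequence i."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence IDs")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids=ids, rows=rows)


def _kmer_distance(seq_a: str, seq_b: str, k: int) -> float:
    ka = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    kb = {seq_b[i : i + k] for i in range(len(seq_b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile(rows_codes: list[np.ndarray], n_letters: int) -> np.ndarray:
    """Column frequency matrix (n_cols x n_letters+1, last index = gap)."""
    arr = np.stack(rows_codes)
    n_rows, n_cols = arr.shape
    freq = np.zeros((n_cols, n_letters + 1))
    for code in range(n_letters + 1):
        freq[:, code] = (arr == code).sum(axis=0)
    return freq / n_rows


def _merge(
    rows_a: list[np.ndarray],
    rows_b: list[np.ndarray],
    S_pad: np.ndarray,
    gap_code: int,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    fa = _profile(rows_a, gap_code)
    fb = _profile(rows_b, gap_code)
    M = fa @ S_pad @ fb.T
    H, E, F = nw_fill(M, gap_open, gap_extend)
    path = nw_traceback(H, E, F, M, gap_open, gap_extend)
    new_a = [np.empty(len(path), dtype=np.int64) for _ in rows_a]
    new_b = [np.empty(len(path), dtype=np.int64) for _ in rows_b]
    for col, (i, j) in enumerate(path):
        for r, row in enumerate(rows_a):
            new_a[r][col] = row[i] if i >= 0 else gap_code
        for r, row in enumerate(rows_b):
            new_b[r][col] = row[j] if j >= 0 else gap_code
    return new_a, new_b


def progressive_align(
    seqs: dict[str, str] | list[tuple[str, str]],
    matrix: str = "blosum62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MSA:
    """Guide-tree progressive alignment of protein sequences.

    A single sequence is returned unchanged as a 1-row MSA. The column
    count is always >= the longest input and every row ungaps back to its
    input sequence.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences to align")
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence IDs")
    if any(not s for _, s in items):
        raise ValueError("cannot align an empty sequence")
    if len(items) == 1:
        return MSA(ids=[items[0][0]], rows=[items[0][1]])

    S, index = load_matrix(matrix)
    gap_code = S.shape[0]
    S_pad = np.zeros((gap_code + 1, gap_code + 1))
    S_pad[:gap_code, :gap_code] = S

    codes = {
        sid: np.array([index[ch] for ch in seq], dtype=np.int64) for sid, seq in items
    }
    n = len(items)
    if n == 2:
        merge_order = [(0, 1)]
    else:
        k = min(3, min(len(s) for _, s in items))
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = _kmer_distance(items[i][1], items[j][1], k)
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
        merge_order = [(int(a), int(b)) for a, b, _, _ in Z]

    clusters: dict[int, tuple[list[str], list[np.ndarray]]] = {
        i: ([sid], [codes[sid]]) for i, (sid, _) in enumerate(items)
    }
    next_id = n
    for a, b in merge_order:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        new_a, new_b = _merge(rows_a, rows_b, S_pad, gap_code, gap_open, gap_extend)
        clusters[next_id] = (ids_a + ids_b, new_a + new_b)
        next_id += 1
    (final_ids, final_rows), = clusters.values()

    letters = {v: k for k, v in index.items()}
    letters[gap_code] = GAP
    aligned = {
        sid: "".join(letters[int(c)] for c in row)
        for sid, row in zip(final_ids, final_rows)
    }
    return MSA(ids=ids, rows=[aligned[sid] for sid in ids])


def mask_gappy_columns(
    msa: MSA, max_gap_fraction: float = 0.5
) -> tuple[MSA, list[int]]:
    """Drop columns whose gap fraction exceeds the threshold.

    Returns the masked MSA and the map from new to original column indices
    (``column_map[new] == old``), used to report residue positions in
    original alignment coordinates.
    """
    n_rows = len(msa.rows)
    keep = [
        c
        for c in range(msa.n_cols)
        if sum(row[c] == GAP for row in msa.rows) / n_rows <= max_gap_fraction
    ]
    if not keep:
        raise ValueError(
            "all columns exceed the gap threshold; raise max_gap_fraction"
        )
    rows = ["".join(row[c] for c in keep) for row in msa.rows]
    return MSA(ids=list(msa.ids), rows=rows), keep
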