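"""Specificity-determining positions (SDPs) between two subtypes.

A column is I-specific when one residue is conserved within subtype I at
fraction >= ``strict`` while appearing in subtype II at fraction
<= 1 - strict (and symmetrically for II-specific). A column specific on
both sides — conserved to different residues in the two subtypes — is the
diagnostic case and is flagged distinctly. Gaps count against conservation
and can never be the conserved residue.
"""

from __future__ import annotations

import pandas as pd

from .alignment import GAP, MSA

CATEGORIES = ("diagnostic", "I-specific", "II-specific", "shared-conserved", "variable")


def _consensus(column: list[str]) -> tuple[str, float]:
    """Most frequent non-gap residue and its fraction of ALL rows."""
    counts: dict[str, int] = {}
    for ch in column:
        if ch != GAP:
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return GAP, 0.0
    best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return best[0], best[1] / len(column)


def classify_columns(
    msa: MSA,
    subtype_labels: dict[str, str],
    strict: float = 1.0,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-column SDP table over an aligned family.

    Returns a DataFrame with one row per column: consensus residue and
    conservation fraction per subtype, boolean specificity flags, and a
    single category (diagnostic > I-specific > II-specific >
    shared-conserved > variable).
    """
    missing = [sid for sid in msa.ids if sid not in subtype_labels]
    if missing:
        raise ValueError(f"subtype labels missing for {missing}")
    group_i = [sid for sid in msa.ids if subtype_labels[sid] == "I"]
    group_ii = [sid for sid in msa.ids if subtype_labels[sid] == "II"]
    if len(group_i) < min_group or len(group_ii) < min_group:
        raise ValueError(
            f"both subtypes need >= {min_group} members "
            f"(got {len(group_i)} and {len(group_ii)})"
        )
    rows_i = [msa.row(sid) for sid in group_i]
    rows_ii = [msa.row(sid) for sid in group_ii]
    records = []
    for col in range(msa.n_cols):
        col_i = [r[col] for r in rows_i]
        col_ii = [r[col] for r in rows_ii]
        cons_i, frac_i = _consensus(col_i)
        cons_ii, frac_ii = _consensus(col_ii)
        freq_i_in_ii = sum(c == cons_i for c in col_ii) / len(col_ii)
        freq_ii_in_i = sum(c == cons_ii for c in col_i) / len(col_i)
        i_specific = frac_i >= strict and freq_i_in_ii <= (1.0 - strict)
        ii_specific = frac_ii >= strict and freq_ii_in_i <= (1.0 - strict)
        if i_specific and ii_specific:
            category = "diagnostic"
        elif i_specific:
            category = "I-specific"
        elif ii_specific:
            category = "II-specific"
        elif cons_i == cons_ii and frac_i >= strict and frac_ii >= strict:
            category = "shared-conserved"
        else:
            category = "variable"
        records.append(
            {
                "column": col,
                "consensus_I": cons_i,
                "frac_I": frac_i,
                "consensus_II": cons_ii,
                "frac_II": frac_ii,
                "I_specific": bool(i_specific),
                "II_specific": bool(ii_specific),
                "category": category,
            }
        )
    return pd.DataFrame(records)


_CATEGORY_TAG = {
    "diagnostic": "D",
    "I-specific": "1",
    "II-specific": "2",
    "shared-conserved": "C",
    "variable": ".",
}
_TAG_CATEGORY = {v: k for k, v in _CATEGORY_TAG.items()}


def sdp_report(
    sdp_table: pd.DataFrame,
    column_map: list[int] | None = None,
    tsv_path=None,
    annotated_fasta_path=None,
    msa: MSA | None = None,
) -> pd.DataFrame:
    """Report SDPs in original alignment coordinates.

    ``column_map`` is the new->original index map from mask_gappy_columns
    (identity if None). Optionally writes sdp.tsv and an annotated aligned
    FASTA whose final ``#SDP`` record carries one category tag per column.
    """
    report = sdp_table.copy()
    if column_map is not None:
        if len(column_map) != len(report):
            raise ValueError("column_map length does not match SDP table")
        report["column"] = [column_map[c] for c in report["column"]]
    if tsv_path is not None:
        cols = [
            "column",
            "category",
            "consensus_I",
            "frac_I",
            "consensus_II",
            "frac_II",
        ]
        report[cols].to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if annotated_fasta_path is not None:
        if msa is None:
            raise ValueError("annotated output requires the masked MSA")
        tags = "".join(_CATEGORY_TAG[c] for c in sdp_table["category"])
        with open(annotated_fasta_path, "w") as fh:
            for sid, row in zip(msa.ids, msa.rows):
                fh.write(f">{sid}\n{row}\n")
            fh.write(f">#SDP\n{tags}\n")
    return report


def parse_annotated_alignment(path) -> tuple[MSA, list[str]]:
    """Read back an annotated alignment; returns (MSA, per-column categories)."""
    ids, rows = [], []
    tags = None
    with open(path) as fh:
        current = None
        buf: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if current is not None:
                    if current == "#SDP":
                        tags = "".join(buf)
                    else:
                        ids.append(current)
                        rows.append("".join(buf))
                current = line[1:].split()[0]
                buf = []
            else:
                buf.append(line)
        if current is not None:
            if current == "#SDP":
                tags = "".join(buf)
            else:
                ids.append(current)
                rows.append("".join(buf))
    if tags is None:
        raise ValueError("no #SDP annotation record found")
    return MSA(ids=ids, rows=rows), [_TAG_CATEGORY[t] for t in tags]
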