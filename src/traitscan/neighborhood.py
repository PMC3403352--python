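"""Operon inference and chromosomal proximity scoring.

Operons are approximated as maximal runs of same-strand consecutive genes
whose intergenic gaps are at most ``max_gap_bp`` (default 100 bp, a common
operon-prediction heuristic; the biological notion of a transcription unit
is not modeled). "Very close" is operationalized as gene-rank distance <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Genome

DEFAULT_MAX_GAP_BP = 100
DEFAULT_RANK_WINDOW = 3
OPERON_WEIGHT = 1.0
NEAR_WEIGHT = 0.5
SCORE_CAP = 0.999


@dataclass
class Operon:
    contig_id: str
    strand: str
    gene_ids: list[str]


@dataclass
class ProximityRecord:
    """Closest-anchor evidence for one candidate gene in one genome."""

    genome_id: str
    candidate_gene_id: str
    anchor_gene_id: str
    distance: int  # gene-rank distance, >= 1
    same_operon: bool
    same_strand: bool

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("candidate and anchor must be distinct genes")
        if self.same_operon and not self.same_strand:
            raise ValueError("same_operon implies same_strand")


def infer_operons(genome: Genome, max_gap_bp: int = DEFAULT_MAX_GAP_BP) -> list[Operon]:
    """Maximal same-strand runs with intergenic gap <= max_gap_bp.

    Singletons are one-gene operons, so operons partition each contig.
    """
    operons: list[Operon] = []
    for contig_id in sorted(genome.contigs):
        genes = genome.contigs[contig_id]
        run: list = []
        for gene in genes:
            if run and gene.strand == run[-1].strand and (
                gene.start - run[-1].end
            ) <= max_gap_bp:
                run.append(gene)
            else:
                if run:
                    operons.append(
                        Operon(contig_id, run[0].strand, [g.gene_id for g in run])
                    )
                run = [gene]
        if run:
            operons.append(Operon(contig_id, run[0].strand, [g.gene_id for g in run]))
    return operons


def proximity(
    genome: Genome,
    candidate_gene_ids: list[str],
    anchor_gene_ids: list[str],
    operons: list[Operon] | None = None,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[ProximityRecord]:
    """Minimal gene-rank distance from each candidate to any anchor.

    Distance is the difference of positional ranks on the shared contig;
    candidate/anchor pairs on different contigs yield no record.
    """
    if operons is None:
        operons = infer_operons(genome, max_gap_bp)
    operon_of = {
        gid: i for i, op in enumerate(operons) for gid in op.gene_ids
    }
    records: list[ProximityRecord] = []
    for contig_id in sorted(genome.contigs):
        genes = genome.contigs[contig_id]
        rank = {g.gene_id: i for i, g in enumerate(genes)}
        strand = {g.gene_id: g.strand for g in genes}
        anchors_here = [g for g in anchor_gene_ids if g in rank]
        for cand in candidate_gene_ids:
            if cand not in rank or not anchors_here:
                continue
            best = None
            for anc in anchors_here:
                if anc == cand:
                    continue
                d = abs(rank[cand] - rank[anc])
                if best is None or d < best[0] or (d == best[0] and anc < best[1]):
                    best = (d, anc)
            if best is None:
                continue
            d, anc = best
            records.append(
                ProximityRecord(
                    genome_id=genome.genome_id,
                    candidate_gene_id=cand,
                    anchor_gene_id=anc,
                    distance=d,
                    same_operon=operon_of.get(cand) == operon_of.get(anc),
                    same_strand=strand[cand] == strand[anc],
                )
            )
    return records


def neighborhood_score(
    proximity_records: list[ProximityRecord],
    n_genomes: int,
    rank_window: int = DEFAULT_RANK_WINDOW,
) -> float:
    """Aggregate neighborhood evidence into s_nbr in [0, 1).

    Per genome the best record contributes w = 1 if same operon, 0.5 if
    within ``rank_window`` gene ranks, else 0; the score is the capped mean
    s = min(0.999, sum(w) / n_genomes).
    """
    if n_genomes <= 0:
        raise ValueError("n_genomes must be positive")
    best_per_genome: dict[str, float] = {}
    for rec in proximity_records:
        if rec.same_operon:
            w = OPERON_WEIGHT
        elif rec.distance <= rank_window:
            w = NEAR_WEIGHT
        else:
            w = 0.0
        prev = best_per_genome.get(rec.genome_id, 0.0)
        if w > prev:
            best_per_genome[rec.genome_id] = w
    return min(SCORE_CAP, sum(best_per_genome.values()) / n_genomes)
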