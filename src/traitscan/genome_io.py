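"""Genome, gene and tree I/O with a fixed internal coordinate model.

Internal coordinates are 0-based half-open; GFF3 files (1-based inclusive)
are converted at the boundary in both directions, so interval arithmetic on
intergenic gaps never needs an off-by-one correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: GFF3 feature types that carry genes; everything else is counted and skipped.
_GENE_FEATURES = {"CDS", "gene"}


@dataclass
class Gene:
    """A protein-coding gene on a contig.

    ``start``/``end`` are 0-based half-open on the contig; ``protein_seq``
    is the translated product (uppercase, 20 canonical letters plus X).
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end "
                f"(got {self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.protein_seq:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")
        bad = set(self.protein_seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id}: non-amino-acid letters {sorted(bad)}"
            )


@dataclass
class Genome:
    """One genome: ordered genes per contig, one record per species."""

    genome_id: str
    taxon_label: str = ""
    contigs: dict[str, list[Gene]] = field(default_factory=dict)

    def genes(self) -> list[Gene]:
        """All genes in deterministic (contig, start, ID) order."""
        out: list[Gene] = []
        for contig_id in sorted(self.contigs):
            out.extend(self.contigs[contig_id])
        return out

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def sort(self) -> None:
        for contig_id in self.contigs:
            self.contigs[contig_id].sort(key=lambda g: (g.start, g.gene_id))


def gff3_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a GFF3 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_1based


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    """Inverse of :func:`gff3_to_internal`."""
    return start + 1, end


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genome(
    fasta_path, gff3_path, genome_id: str | None = None, taxon_label: str = ""
) -> Genome:
    """Read a genome from a protein FASTA plus a GFF3 feature file.

    Only ``CDS``/``gene`` features are consumed (other types are counted and
    logged). FASTA record IDs must match the GFF3 ``ID`` attributes; a CDS
    with no protein is a hard error naming the offending ID. Duplicate
    coordinates are resolved deterministically (keep first by ID order) with
    a warning.
    """
    proteins = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if genome_id is None:
        genome_id = str(gff3_path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    genome = Genome(genome_id=genome_id, taxon_label=taxon_label)
    n_skipped = 0
    seen_ids: set[str] = set()
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig_id, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype not in _GENE_FEATURES:
                n_skipped += 1
                continue
            gene_id = _parse_gff3_attributes(attrs).get("ID")
            if gene_id is None:
                raise ValueError(f"GFF3 feature without ID attribute: {line!r}")
            if gene_id in seen_ids:
                # gene + CDS pairs share an ID; keep the first occurrence
                continue
            seen_ids.add(gene_id)
            if gene_id not in proteins:
                raise ValueError(
                    f"annotated CDS {gene_id!r} has no protein in {fasta_path}"
                )
            s, e = gff3_to_internal(int(start), int(end))
            gene = Gene(gene_id, contig_id, s, e, strand, proteins[gene_id])
            genome.contigs.setdefault(contig_id, []).append(gene)
    if n_skipped:
        logger.info("read_genome(%s): skipped %d non-gene features", genome_id, n_skipped)
    # deterministic order + duplicate-coordinate resolution
    for contig_id, genes in genome.contigs.items():
        genes.sort(key=lambda g: (g.start, g.gene_id))
        deduped: list[Gene] = []
        for g in genes:
            if deduped and (g.start, g.end) == (deduped[-1].start, deduped[-1].end):
                warnings.warn(
                    f"duplicate coordinates on {contig_id}: keeping "
                    f"{deduped[-1].gene_id}, dropping {g.gene_id}"
                )
                continue
            deduped.append(g)
        genome.contigs[contig_id] = deduped
    return genome


def write_genome(genome: Genome, fasta_path, gff3_path) -> None:
    """Write a genome back to protein FASTA + GFF3 (round-trip inverse)."""
    records = []
    lines = ["##gff-version 3"]
    for gene in genome.genes():
        records.append(SeqRecord(Seq(gene.protein_seq), id=gene.gene_id, description=""))
        s1, e1 = internal_to_gff3(gene.start, gene.end)
        lines.append(
            "\t".join(
                [
                    gene.contig_id,
                    "traitscan",
                    "CDS",
                    str(s1),
                    str(e1),
                    ".",
                    gene.strand,
                    "0",
                    f"ID={gene.gene_id}",
                ]
            )
        )
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_newick(path) -> dendropy.Tree:
    """Read a Newick tree; malformed input raises ValueError with position."""
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy reports line/column in its message
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc


def read_newick_string(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc


def write_profile_tsv(profile, path) -> None:
    """Write a phyletic profile as TSV (header = family IDs, rows = genomes)."""
    if profile.matrix.empty:
        raise ValueError("refusing to write an empty profile")
    profile.matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_profile_tsv(path):
    """Inverse of :func:`write_profile_tsv`."""
    import pandas as pd

    from .profiles import PhyleticProfile

    matrix = pd.read_csv(path, sep="\t", index_col="genome_id")
    return PhyleticProfile(matrix=matrix.astype(int))
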