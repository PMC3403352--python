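"""End-to-end orchestration: homology -> profiles -> trait calls ->
neighborhood -> linkage -> MSA -> tree -> subtypes -> SDP.

Every stage reads and writes plain-text artifacts in the run's output
directory, so partial reruns from cached stages equal a fresh full run, and
two runs with the same config and seed are byte-identical (the run report
contains no timestamps and all randomness flows from the config seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import MSA, mask_gappy_columns, progressive_align
from .genome_io import Genome, read_genome
from .homology import OrthologMap, search_genomes
from .neighborhood import infer_operons, neighborhood_score, proximity
from .phylo import bootstrap_support, neighbor_joining, protein_distance, split_subtypes
from .profiles import (
    RESOLVING_STATUSES,
    PhyleticProfile,
    build_profile,
    call_traits,
    detect_fusions,
    rank_partners,
)

STAGES = (
    "homology",
    "profiles",
    "trait_calls",
    "neighborhood",
    "linkage",
    "msa",
    "tree",
    "subtypes",
    "sdp",
)

#: artifact file -> subcommand that produces it (for actionable errors)
PRODUCERS = {
    "hits.tsv": "profile",
    "orthologs.tsv": "profile",
    "profile.tsv": "profile",
    "trait_calls.tsv": "profile",
    "operons.tsv": "link",
    "proximity.tsv": "link",
    "linkage_report.tsv": "link",
    "aligned.fasta": "tree",
    "masked.fasta": "tree",
    "masked_columns.tsv": "tree",
    "genetree.nwk": "tree",
    "subtype_labels.tsv": "tree",
    "sdp.tsv": "sdp",
    "sdp_annotated.fasta": "sdp",
}

DEFAULT_ANCHORS = ["ruvA", "ruvB", "ruvC", "recU"]


@dataclass
class RunConfig:
    """One config drives every stage; flags override file values.

    Only the input paths and the random seed have no default.
    """

    genome_dir: str
    seeds_path: str
    out_dir: str
    seed: int
    taxa_path: str | None = None
    reference_tree: str | None = None
    evalue_cutoff: float = 0.1
    matrix: str = "blosum62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.318
    K: float = 0.134
    max_gap_bp: int = 100
    rank_window: int = 3
    anchor_families: list[str] = field(default_factory=lambda: list(DEFAULT_ANCHORS))
    tree_family: str = "yebC"
    max_gap_fraction: float = 0.5
    sdp_strict: float = 0.9
    sdp_min_group: int = 3
    bootstrap_replicates: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must provide a random seed")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _require(out: Path, filename: str) -> Path:
    path = out / filename
    if not path.exists():
        producer = PRODUCERS.get(filename, "run")
        raise FileNotFoundError(
            f"missing artifact {filename}; run `traitscan {producer}` first"
        )
    return path


def load_genomes(config: RunConfig) -> list[Genome]:
    gdir = Path(config.genome_dir)
    taxa: dict[str, str] = {}
    if config.taxa_path and Path(config.taxa_path).exists():
        t = pd.read_csv(config.taxa_path, sep="\t")
        taxa = dict(zip(t.genome_id, t.taxon))
    genomes = []
    for fasta in sorted(gdir.glob("*.faa")):
        gff3 = fasta.with_suffix(".gff3")
        genome_id = fasta.stem
        genomes.append(
            read_genome(fasta, gff3, genome_id, taxon_label=taxa.get(genome_id, ""))
        )
    if not genomes:
        raise FileNotFoundError(f"no .faa/.gff3 genome pairs in {gdir}")
    return genomes


def load_seeds(config: RunConfig) -> dict[str, dict[str, str]]:
    from Bio import SeqIO

    seeds: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(config.seeds_path), "fasta"):
        family = rec.id
        for token in rec.description.split():
            if token.startswith("family="):
                family = token.split("=", 1)[1]
        seeds.setdefault(family, {})[rec.id] = str(rec.seq).upper()
    if not seeds:
        raise ValueError(f"no seed sequences in {config.seeds_path}")
    return seeds


def _read_orthologs(out: Path) -> OrthologMap:
    df = pd.read_csv(_require(out, "orthologs.tsv"), sep="\t")
    omap = OrthologMap(families=sorted(df.family.unique()))
    for fam in omap.families:
        omap.assignments[fam] = {}
        omap.paralogs[fam] = {}
    for row in df.itertuples():
        if row.kind == "ortholog":
            omap.assignments[row.family][row.genome_id] = row.gene_id
        else:
            omap.paralogs[row.family].setdefault(row.genome_id, []).append(row.gene_id)
    return omap


def stage_profile(config: RunConfig) -> dict[str, int]:
    """Homology search, BBH orthology, phyletic profile and trait calls."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = load_genomes(config)
    seeds = load_seeds(config)
    hits, omap = search_genomes(
        genomes,
        seeds,
        evalue_cutoff=config.evalue_cutoff,
        matrix=config.matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        lambda_=config.lambda_,
        K=config.K,
    )
    hits.to_csv(out / "hits.tsv", sep="\t", index=False, float_format="%.6g")
    rows = []
    for fam in omap.families:
        for genome_id, gene_id in sorted(omap.assignments[fam].items()):
            rows.append((fam, genome_id, gene_id, "ortholog"))
        for genome_id, genes in sorted(omap.paralogs[fam].items()):
            for gene_id in genes:
                rows.append((fam, genome_id, gene_id, "paralog"))
    pd.DataFrame(rows, columns=["family", "genome_id", "gene_id", "kind"]).to_csv(
        out / "orthologs.tsv", sep="\t", index=False
    )
    profile = build_profile(omap, genomes)
    profile.matrix.to_csv(out / "profile.tsv", sep="\t", index_label="genome_id")
    calls = call_traits(profile)
    calls.to_csv(out / "trait_calls.tsv", sep="\t")
    return {
        "homology": len(hits),
        "profiles": int(profile.matrix.to_numpy().sum()),
        "trait_calls": int((calls.status != "absent").sum()),
    }


def stage_link(config: RunConfig) -> dict[str, int]:
    """Operons, anchor proximity and the combined linkage ranking."""
    out = Path(config.out_dir)
    genomes = load_genomes(config)
    seeds = load_seeds(config)
    omap = _read_orthologs(out)
    profile = PhyleticProfile(
        matrix=pd.read_csv(_require(out, "profile.tsv"), sep="\t", index_col="genome_id")
    )
    calls = pd.read_csv(_require(out, "trait_calls.tsv"), sep="\t", index_col="genome_id")
    hits = pd.read_csv(_require(out, "hits.tsv"), sep="\t")

    anchor_genes: dict[str, list[str]] = {}
    for fam in config.anchor_families:
        for genome_id, gene_id in omap.assignments.get(fam, {}).items():
            anchor_genes.setdefault(genome_id, []).append(gene_id)

    operon_rows, prox_rows = [], []
    nbr_scores: dict[str, float] = {}
    candidate_families = [
        f for f in profile.families if f not in set(config.anchor_families)
    ]
    records_by_family = {f: [] for f in candidate_families}
    for genome in genomes:
        operons = infer_operons(genome, config.max_gap_bp)
        for i, op in enumerate(operons):
            operon_rows.append(
                (genome.genome_id, i, op.contig_id, op.strand, ",".join(op.gene_ids))
            )
        anchors = sorted(anchor_genes.get(genome.genome_id, []))
        if not anchors:
            continue
        for fam in candidate_families:
            cand = []
            gene_id = omap.assignments.get(fam, {}).get(genome.genome_id)
            if gene_id:
                cand.append(gene_id)
            cand += omap.paralogs.get(fam, {}).get(genome.genome_id, [])
            if not cand:
                continue
            recs = proximity(genome, sorted(cand), anchors, operons, config.max_gap_bp)
            records_by_family[fam].extend(recs)
            for r in recs:
                prox_rows.append(
                    (
                        r.genome_id,
                        fam,
                        r.candidate_gene_id,
                        r.anchor_gene_id,
                        r.distance,
                        int(r.same_operon),
                        int(r.same_strand),
                    )
                )
    for fam in candidate_families:
        nbr_scores[fam] = neighborhood_score(
            records_by_family[fam], len(genomes), config.rank_window
        )
    pd.DataFrame(
        operon_rows, columns=["genome_id", "operon", "contig_id", "strand", "gene_ids"]
    ).to_csv(out / "operons.tsv", sep="\t", index=False)
    pd.DataFrame(
        prox_rows,
        columns=[
            "genome_id",
            "family",
            "candidate_gene_id",
            "anchor_gene_id",
            "distance",
            "same_operon",
            "same_strand",
        ],
    ).to_csv(out / "proximity.tsv", sep="\t", index=False)

    # anchor presence = the trait signature (RuvAB plus either resolvase)
    anchor_vector = (
        calls.loc[profile.genomes, "status"].isin(RESOLVING_STATUSES).astype(int).to_numpy()
    )
    fusion_pairs = detect_fusions(hits, seeds)
    report = rank_partners(
        profile,
        config.anchor_families,
        neighborhood_scores=nbr_scores,
        fusion_pairs=fusion_pairs,
        anchor_vector=anchor_vector,
    )
    report.to_csv(out / "linkage_report.tsv", sep="\t", index=False, float_format="%.10g")
    return {"neighborhood": len(prox_rows), "linkage": len(report)}


def stage_tree(config: RunConfig) -> dict[str, int]:
    """Align the focal family, build the NJ tree, bootstrap and split."""
    out = Path(config.out_dir)
    genomes = load_genomes(config)
    omap = _read_orthologs(out)
    members: dict[str, str] = {}
    gene_lookup = {
        (g.genome_id, gene.gene_id): gene.protein_seq
        for g in genomes
        for gene in g.genes()
    }
    for genome_id, gene_id in sorted(omap.assignments.get(config.tree_family, {}).items()):
        members[genome_id] = gene_lookup[(genome_id, gene_id)]
    if len(members) < 3:
        raise ValueError(
            f"family {config.tree_family} has {len(members)} orthologs; need >= 3"
        )
    msa = progressive_align(
        members, matrix=config.matrix, gap_open=config.gap_open, gap_extend=config.gap_extend
    )
    msa.to_fasta(out / "aligned.fasta")
    masked, column_map = mask_gappy_columns(msa, config.max_gap_fraction)
    masked.to_fasta(out / "masked.fasta")
    pd.DataFrame(
        {"masked_column": range(len(column_map)), "original_column": column_map}
    ).to_csv(out / "masked_columns.tsv", sep="\t", index=False)
    if config.bootstrap_replicates > 0 and len(masked.rows) >= 4:
        gt = bootstrap_support(
            masked, n_replicates=config.bootstrap_replicates, seed=config.seed
        )
        tree = gt.tree
    else:
        D, labels = protein_distance(masked)
        tree = neighbor_joining(D, labels)
    with open(out / "genetree.nwk", "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))
    subtypes = split_subtypes(tree)
    pd.DataFrame(
        sorted(subtypes.items()), columns=["genome_id", "subtype"]
    ).to_csv(out / "subtype_labels.tsv", sep="\t", index=False)
    return {
        "msa": msa.n_cols,
        "tree": len(members),
        "subtypes": sum(v == "I" for v in subtypes.values()),
    }


def stage_sdp(config: RunConfig) -> dict[str, int]:
    """Classify masked alignment columns into SDP categories."""
    from .sdp import classify_columns, sdp_report

    out = Path(config.out_dir)
    masked = MSA.from_fasta(_require(out, "masked.fasta"))
    column_map = list(
        pd.read_csv(_require(out, "masked_columns.tsv"), sep="\t")["original_column"]
    )
    labels_df = pd.read_csv(_require(out, "subtype_labels.tsv"), sep="\t")
    labels = dict(zip(labels_df.genome_id, labels_df.subtype))
    table = classify_columns(
        masked, labels, strict=config.sdp_strict, min_group=config.sdp_min_group
    )
    sdp_report(
        table,
        column_map,
        tsv_path=out / "sdp.tsv",
        annotated_fasta_path=out / "sdp_annotated.fasta",
        msa=masked,
    )
    return {"sdp": int((table.category == "diagnostic").sum())}


def stage_report(config: RunConfig, counts: dict[str, int] | None = None) -> dict:
    """Aggregate artifacts into a machine-readable run report."""
    out = Path(config.out_dir)
    checksums = {}
    for name in sorted(PRODUCERS):
        path = out / name
        if path.exists():
            checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": list(STAGES),
        "counts": counts or {},
        "checksums": checksums,
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def compute_linkage(
    genomes,
    seeds,
    anchor_families=tuple(DEFAULT_ANCHORS),
    evalue_cutoff: float = 0.1,
    max_gap_bp: int = 100,
    rank_window: int = 3,
):
    """In-memory homology -> profile -> trait -> neighborhood -> ranking.

    Convenience wrapper used when the file-based stage interface is not
    needed; returns (profile, trait_calls, linkage_report, ortholog_map).
    """
    anchor_families = list(anchor_families)
    _, omap = search_genomes(genomes, seeds, evalue_cutoff, with_spans=False)
    profile = build_profile(omap, genomes)
    calls = call_traits(profile)
    anchor_genes: dict[str, list[str]] = {}
    for fam in anchor_families:
        for genome_id, gene_id in omap.assignments.get(fam, {}).items():
            anchor_genes.setdefault(genome_id, []).append(gene_id)
    candidates = [f for f in profile.families if f not in set(anchor_families)]
    records = {f: [] for f in candidates}
    for genome in genomes:
        operons = infer_operons(genome, max_gap_bp)
        anchors = sorted(anchor_genes.get(genome.genome_id, []))
        if not anchors:
            continue
        for fam in candidates:
            gene_id = omap.assignments.get(fam, {}).get(genome.genome_id)
            cand = ([gene_id] if gene_id else []) + omap.paralogs.get(fam, {}).get(
                genome.genome_id, []
            )
            if cand:
                records[fam].extend(
                    proximity(genome, sorted(cand), anchors, operons, max_gap_bp)
                )
    nbr = {
        f: neighborhood_score(records[f], len(genomes), rank_window)
        for f in candidates
    }
    anchor_vector = (
        calls.loc[profile.genomes, "status"]
        .isin(RESOLVING_STATUSES)
        .astype(int)
        .to_numpy()
    )
    report = rank_partners(
        profile,
        anchor_families,
        neighborhood_scores=nbr,
        anchor_vector=anchor_vector,
    )
    return profile, calls, report, omap


def run_full(config: RunConfig) -> dict:
    """Execute all stages in order; abort on the first failure, naming it."""
    counts: dict[str, int] = {}
    for name, fn in (
        ("profile", stage_profile),
        ("link", stage_link),
        ("tree", stage_tree),
        ("sdp", stage_sdp),
    ):
        try:
            counts.update(fn(config))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return stage_report(config, counts)
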