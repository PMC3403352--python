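"""Synthetic genomes with planted statistical structure.

Every downstream stage of the pipeline is exercised against ground truth
produced here:

* gene-family presence/absence evolving as a two-state (gain/loss) Markov
  chain along a Yule species tree;
* a correlated "trait" set (ruvA/ruvB plus a resolvase, ruvC or recU) and a
  planted partner family ("yebC") whose presence tracks the trait set with
  a configurable linkage strength;
* operon-level co-localization of the partner immediately downstream of the
  resolvase gene in a configurable fraction of co-occurring genomes;
* a two-subtype protein family for the partner, with planted
  subtype-diagnostic alignment columns.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` substreams, so outputs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from math import exp
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .genome_io import Gene, Genome, write_genome

AA20 = "ACDEFGHIKLMNPQRSTVWY"

ANCHOR_FAMILIES = ("ruvA", "ruvB", "ruvC", "recU")
PARTNER_FAMILY = "yebC"


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Rates are per unit branch length of the (ultrametric) species tree.
    ``subtype_divergence`` is the per-site substitution probability from a
    subtype ancestor to a tip sequence; the two subtype ancestors themselves
    differ at non-diagnostic sites at a quarter of that rate each, so
    incidental (non-planted) fully-conserved between-subtype differences
    stay rare.
    """

    n_genomes: int = 50
    birth_rate: float = 0.3
    loss_rate: float = 0.3
    n_decoy_families: int = 20
    linkage_strength: float = 0.95
    operon_gap_bp: int = 50
    operon_fraction: float = 0.75
    subtype_divergence: float = 0.3
    n_diagnostic_columns: int = 10
    seed: int = 0
    protein_len: int = 200
    genome_divergence: float = 0.05
    recu_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.birth_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.linkage_strength <= 1.0:
            raise ValueError("linkage_strength must be in [0, 1]")
        if not 0.0 <= self.operon_fraction <= 1.0:
            raise ValueError("operon_fraction must be in [0, 1]")
        if self.n_diagnostic_columns < 1:
            raise ValueError("n_diagnostic_columns must be >= 1")
        if self.protein_len < self.n_diagnostic_columns:
            raise ValueError("sequence length smaller than n_diagnostic_columns")
        if self.seed is None:
            raise ValueError("seed is required")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["tree", "content", "sequence", "subtype", "layout"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_species_tree(n_genomes: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Yule (pure-birth) species tree with ``n_genomes`` extant leaves.

    Ultrametric with strictly positive branch lengths (a final exponential
    stretch is added after the last speciation so terminal branches never
    have zero length). Leaves are labeled G001.. in a deterministic order.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    rnd = random.Random(int(seed) % 2**31)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    first = [dendropy.Node(), dendropy.Node()]
    for child in first:
        root.add_child(child)
    pending = {id(nd): 0.0 for nd in first}
    active = list(first)
    while len(active) < n_genomes:
        dt = rnd.expovariate(birth_rate * len(active))
        for nd in active:
            pending[id(nd)] += dt
        nd = active.pop(rnd.randrange(len(active)))
        nd.edge.length = pending.pop(id(nd))
        kids = [dendropy.Node(), dendropy.Node()]
        for kid in kids:
            nd.add_child(kid)
            pending[id(kid)] = 0.0
        active.extend(kids)
    dt = rnd.expovariate(birth_rate * len(active))
    for nd in active:
        nd.edge.length = pending[id(nd)] + dt
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(f"G{i + 1:03d}")
    return tree


def assign_taxa(tree: dendropy.Tree) -> dict[str, str]:
    """Group leaves into 'phyla' by the clades two splits below the root."""
    clades: list[list[str]] = []
    for child in tree.seed_node.child_nodes():
        grand = child.child_nodes()
        if not grand:
            clades.append([child.taxon.label])
            continue
        for g in grand:
            clades.append([lf.taxon.label for lf in g.leaf_iter()])
    out = {}
    for i, leaves in enumerate(clades):
        for label in leaves:
            out[label] = f"phylum_{i + 1:02d}"
    return out


def _evolve_binary(tree, gain: float, loss: float, root_state: int, rng) -> dict[str, int]:
    """Two-state Markov chain along the tree; returns leaf states."""
    total = gain + loss
    pi1 = gain / total if total > 0 else 0.0
    states: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = root_state
            continue
        parent = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        if total == 0.0:
            p_present = float(parent)
        else:
            p_present = pi1 + (parent - pi1) * exp(-total * t)
        states[id(node)] = int(rng.random() < p_present)
    return {lf.taxon.label: states[id(lf)] for lf in tree.leaf_node_iter()}


def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate(seq: str, rate: float, rng, frozen: set[int] | None = None) -> str:
    """Mutate each site independently with probability ``rate`` to one of the
    19 other residues; ``frozen`` sites are never touched."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        if frozen and int(i) in frozen:
            continue
        alternatives = AA20.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def evolve_subtype_family(tree_or_ids, config: SimConfig, rng=None):
    """Two-subtype protein family with planted diagnostic columns.

    Members are split into two balanced clades (I and II). The root sequence
    spawns one ancestor per clade (non-diagnostic sites mutated at
    ``subtype_divergence / 4`` each); each member then mutates from its
    clade ancestor at ``subtype_divergence``. The ``n_diagnostic_columns``
    planted columns are fixed to residue a in clade I and b != a in clade II
    and are exempt from further mutation, so they differ between clades in
    every member regardless of divergence.

    Returns (sequences, labels, diagnostic_columns, diagnostic_residues).
    """
    if rng is None:
        rng = _streams(config.seed)["subtype"]
    if hasattr(tree_or_ids, "leaf_node_iter"):
        member_ids = [lf.taxon.label for lf in tree_or_ids.leaf_node_iter()]
    else:
        member_ids = list(tree_or_ids)
    L = config.protein_len
    k = config.n_diagnostic_columns
    if L < k:
        raise ValueError("sequence length smaller than n_diagnostic_columns")
    root = _random_protein(rng, L)
    diag_cols = sorted(int(c) for c in rng.choice(L, size=k, replace=False))
    diag_residues: dict[int, tuple[str, str]] = {}
    for col in diag_cols:
        a, b = rng.choice(len(AA20), size=2, replace=False)
        diag_residues[col] = (AA20[int(a)], AA20[int(b)])
    frozen = set(diag_cols)
    anc = {}
    for label, res_idx in (("I", 0), ("II", 1)):
        seq = _mutate(root, config.subtype_divergence / 4.0, rng, frozen)
        chars = list(seq)
        for col in diag_cols:
            chars[col] = diag_residues[col][res_idx]
        anc[label] = "".join(chars)
    # balanced random clade assignment
    order = list(member_ids)
    perm = rng.permutation(len(order))
    half = (len(order) + 1) // 2
    labels = {}
    for rank, idx in enumerate(perm):
        labels[order[int(idx)]] = "I" if rank < half else "II"
    seqs = {
        mid: _mutate(anc[labels[mid]], config.subtype_divergence, rng, frozen)
        for mid in member_ids
    }
    return seqs, labels, diag_cols, diag_residues


@dataclass
class SimResult:
    """Everything the downstream pipeline and the tests need."""

    config: SimConfig
    tree: dendropy.Tree
    genomes: list[Genome]
    presence: pd.DataFrame  # genomes x families, the planted truth profile
    seeds: dict[str, dict[str, str]]  # family -> {seed_id: sequence}
    truth: dict


def evolve_gene_content(tree: dendropy.Tree, config: SimConfig) -> SimResult:
    """Plant family content, sequences and gene order on a species tree."""
    rngs = _streams(config.seed)
    rng_content = rngs["content"]
    rng_seq = rngs["sequence"]
    rng_layout = rngs["layout"]

    leaf_ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    taxa = assign_taxa(tree)
    decoys = [f"dec{i:03d}" for i in range(config.n_decoy_families)]
    families = ["ruvA", "ruvB", "ruvC", "recU", PARTNER_FAMILY] + decoys

    gain, loss = config.birth_rate, config.loss_rate
    pi1 = gain / (gain + loss) if gain + loss > 0 else 0.0

    trait = _evolve_binary(tree, gain, loss, root_state=1, rng=rng_content)
    resolvase = {
        g: ("recU" if rng_content.random() < config.recu_fraction else "ruvC")
        for g in leaf_ids
    }
    partner = {}
    for g in leaf_ids:
        match = rng_content.random() < config.linkage_strength
        partner[g] = trait[g] if match else 1 - trait[g]
    decoy_presence = {}
    for fam in decoys:
        root_state = int(rng_content.random() < pi1) if gain + loss > 0 else 1
        decoy_presence[fam] = _evolve_binary(tree, gain, loss, root_state, rng_content)

    presence = pd.DataFrame(0, index=leaf_ids, columns=families, dtype=int)
    for g in leaf_ids:
        if trait[g]:
            presence.loc[g, "ruvA"] = 1
            presence.loc[g, "ruvB"] = 1
            presence.loc[g, resolvase[g]] = 1
        presence.loc[g, PARTNER_FAMILY] = partner[g]
        for fam in decoys:
            presence.loc[g, fam] = decoy_presence[fam][g]

    # ancestral sequences; the partner family carries the two-subtype model
    ancestral = {
        fam: _random_protein(rng_seq, config.protein_len)
        for fam in families
        if fam != PARTNER_FAMILY
    }
    sub_seqs, sub_labels, diag_cols, diag_residues = evolve_subtype_family(
        leaf_ids, config, rngs["subtype"]
    )

    operon_placed: list[str] = []
    genomes: list[Genome] = []
    for g in leaf_ids:
        blocks: list[list[tuple[str, str, str]]] = []  # [(family, seq, strand)]
        anchor_strand = "+" if rng_layout.random() < 0.5 else "-"
        anchor_block: list[tuple[str, str, str]] = []
        if trait[g]:
            for fam in ("ruvA", "ruvB", resolvase[g]):
                seq = _mutate(ancestral[fam], config.genome_divergence, rng_seq)
                anchor_block.append((fam, seq, anchor_strand))
        in_operon = (
            bool(trait[g])
            and partner[g] == 1
            and rng_layout.random() < config.operon_fraction
        )
        if partner[g]:
            if in_operon:
                anchor_block.append((PARTNER_FAMILY, sub_seqs[g], anchor_strand))
                operon_placed.append(g)
            else:
                strand = "+" if rng_layout.random() < 0.5 else "-"
                blocks.append([(PARTNER_FAMILY, sub_seqs[g], strand)])
        if anchor_block:
            blocks.append(anchor_block)
        for fam in decoys:
            if decoy_presence[fam][g]:
                seq = _mutate(ancestral[fam], config.genome_divergence, rng_seq)
                strand = "+" if rng_layout.random() < 0.5 else "-"
                blocks.append([(fam, seq, strand)])
        order = rng_layout.permutation(len(blocks))
        genome = Genome(genome_id=g, taxon_label=taxa[g])
        cursor = int(rng_layout.integers(0, 500))
        contig = "chr1"
        genes: list[Gene] = []
        for bi in order:
            block = blocks[int(bi)]
            for k, (fam, seq, strand) in enumerate(block):
                start = cursor
                end = start + 3 * len(seq)
                genes.append(Gene(f"{g}_{fam}", contig, start, end, strand, seq))
                if k + 1 < len(block):
                    is_partner_next = block[k + 1][0] == PARTNER_FAMILY
                    gap = (
                        int(rng_layout.integers(0, config.operon_gap_bp + 1))
                        if is_partner_next
                        else int(rng_layout.integers(5, 41))
                    )
                else:
                    gap = int(rng_layout.integers(120, 401))
                cursor = end + gap
        genome.contigs[contig] = genes
        genome.sort()
        genomes.append(genome)

    seeds = {
        fam: {f"{fam}_seed": ancestral[fam]}
        for fam in families
        if fam != PARTNER_FAMILY
    }
    # the partner seed is the family-wide column consensus
    seeds[PARTNER_FAMILY] = {f"{PARTNER_FAMILY}_seed": _partner_seed(sub_seqs, sub_labels)}

    truth = {
        "families": families,
        "anchors": ["ruvA", "ruvB", "ruvC", "recU"],
        "partner": PARTNER_FAMILY,
        "presence": {fam: {g: int(presence.loc[g, fam]) for g in leaf_ids} for fam in families},
        "trait": {g: int(trait[g]) for g in leaf_ids},
        "resolvase": {g: resolvase[g] for g in leaf_ids if trait[g]},
        "operon_placed": sorted(operon_placed),
        "subtype_labels": sub_labels,
        "diagnostic_columns": diag_cols,
        "diagnostic_residues": {str(c): list(diag_residues[c]) for c in diag_cols},
        "taxa": taxa,
    }
    return SimResult(
        config=config,
        tree=tree,
        genomes=genomes,
        presence=presence,
        seeds=seeds,
        truth=truth,
    )


def _partner_seed(sub_seqs: dict[str, str], sub_labels: dict[str, str]) -> str:
    """Column-majority consensus of the partner family (deterministic)."""
    members = sorted(sub_seqs)
    length = len(sub_seqs[members[0]])
    out = []
    for col in range(length):
        counts: dict[str, int] = {}
        for m in members:
            ch = sub_seqs[m][col]
            counts[ch] = counts.get(ch, 0) + 1
        out.append(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    return "".join(out)


def simulate_dataset(config: SimConfig, out_dir=None) -> SimResult:
    """Simulate a full dataset; optionally write it to ``out_dir``.

    Writes per-genome FASTA+GFF3, the seed FASTA, the species tree (Newick)
    and truth.json so every stage can be run from files alone.
    """
    tree = simulate_species_tree(config.n_genomes, config.seed)
    result = evolve_gene_content(tree, config)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        for genome in result.genomes:
            write_genome(
                genome,
                out / "genomes" / f"{genome.genome_id}.faa",
                out / "genomes" / f"{genome.genome_id}.gff3",
            )
        with open(out / "seeds.faa", "w") as fh:
            for fam in sorted(result.seeds):
                for seed_id, seq in sorted(result.seeds[fam].items()):
                    fh.write(f">{seed_id} family={fam}\n{seq}\n")
        result.tree.write(path=str(out / "tree.nwk"), schema="newick")
        with open(out / "truth.json", "w") as fh:
            json.dump(result.truth, fh, indent=1, sort_keys=True)
        with open(out / "taxa.tsv", "w") as fh:
            fh.write("genome_id\ttaxon\n")
            for g in sorted(result.truth["taxa"]):
                fh.write(f"{g}\t{result.truth['taxa'][g]}\n")
        with open(out / "sim_config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=1, sort_keys=True)
    return result
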