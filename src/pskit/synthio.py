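"""Synthetic species-complex generator with a full ground-truth set.

The simulator emulates the statistical structure a genome-based taxonomy
analysis assumes: a rooted tree whose leaves fall into genomovar clades
(short within-clade, long between-clade paths, in substitutions/site),
gene content evolving per family as a two-state gain/loss Markov process
along that tree, Jukes-Cantor sequence evolution of every family, and an
optionally implanted ordered five-gene marker cluster (an ectABCD-ask
analogue) that can be deleted gene-wise from chosen genomes.

Every stochastic choice flows from ``SimConfig.seed``, so identical
configurations produce byte-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from skbio import TreeNode

from .orthopan import PanMatrix
from .records import Gene, GenomeRecord, read_genome, write_fasta, write_gff3

MARKER_GENES = ("ectA", "ectB", "ectC", "ectD", "ask")
_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# Fixed, complex-wide codon-usage bias.  Real genomes carry a genus-level
# oligonucleotide signature (the basis of the TETRA statistic); drawing
# codons non-uniformly -- same distribution for every simulated genome --
# reproduces that shared signature without affecting per-site divergence.
_CODON_WEIGHTS = np.array(
    [1.0 + 15.0 * (((i * 2654435761) % 97) / 96.0) for i in range(len(_NONSTOP_CODONS))]
)
_CODON_PROBS = _CODON_WEIGHTS / _CODON_WEIGHTS.sum()


@dataclass
class SimConfig:
    """Study-design knobs for one synthetic species complex.

    Rates are events per unit branch length; branch lengths (and the
    divergence fields) are in expected substitutions per site, so e.g.
    ``within_divergence=0.01`` yields within-genomovar ANI around 98%.
    """

    n_genomovars: int = 3
    genomes_per_genomovar: int = 4
    root_families: int = 180
    accessory_pool: int = 120  # families absent at the root, gainable later
    gain_rate: float = 1.2
    loss_rate: float = 0.25
    within_divergence: float = 0.01
    between_divergence: float = 0.06
    gene_length: int = 900
    spacer_length: int = 60
    n_contigs: int = 1
    implant_cluster: bool = False
    drop_cluster_gene_in: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomovars < 1 or self.genomes_per_genomovar < 1:
            raise ValueError("genome counts must be positive")
        if min(self.gain_rate, self.loss_rate, self.within_divergence,
               self.between_divergence) < 0:
            raise ValueError("rates and divergences must be non-negative")
        if self.gene_length < 30:
            raise ValueError("gene_length must be >= 30")
        if self.gene_length % 3:
            raise ValueError("gene_length must be divisible by 3")
        if self.n_genomovars > 1 and self.between_divergence < self.within_divergence:
            raise ValueError("between_divergence must be >= within_divergence")


@dataclass
class TruthSet:
    """Ground truth recorded during simulation, for recovery tests."""

    true_tree: TreeNode
    true_genomovar_labels: dict[str, str]
    true_pan_matrix: PanMatrix
    true_events: dict[str, tuple[int, int]]  # child-node name -> (gains, losses)
    true_cluster_status: dict[str, str]  # genome -> complete | partial | absent

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TruthSet)
            and newick(self.true_tree) == newick(other.true_tree)
            and self.true_genomovar_labels == other.true_genomovar_labels
            and self.true_pan_matrix == other.true_pan_matrix
            and self.true_events == other.true_events
            and self.true_cluster_status == other.true_cluster_status
        )


@dataclass
class SimulatedDataset:
    genomes: list[GenomeRecord]
    truth: TruthSet
    config: SimConfig
    gene_families: dict[tuple[str, str], str]  # (genome, gene id) -> family

    def genome(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def proteomes(self) -> dict[str, dict[str, str]]:
        return {g.genome_id: g.proteome for g in self.genomes}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimulatedDataset)
            and self.genomes == other.genomes
            and self.truth == other.truth
            and self.gene_families == other.gene_families
        )


def newick(tree: TreeNode) -> str:
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def _random_ultrametric(leaves: list[str], height: float, rng) -> TreeNode:
    """Random binary topology over `leaves`, node placed at `height` above tips."""
    if len(leaves) == 1:
        return TreeNode(name=leaves[0], length=height)
    k = int(rng.integers(1, len(leaves)))
    order = rng.permutation(len(leaves))
    parts = ([leaves[i] for i in order[:k]], [leaves[i] for i in order[k:]])
    node = TreeNode()
    for part in parts:
        child_height = 0.0 if len(part) == 1 else height * float(rng.uniform(0.5, 0.9))
        child = _random_ultrametric(part, child_height, rng)
        child.length = height - child_height
        node.append(child)
    return node


def _join_clades(clades: list[tuple[TreeNode, float]], height: float,
                 floor: float, rng) -> tuple[TreeNode, float]:
    """Random binary backbone over genomovar clades; joins sit at >= floor."""
    if len(clades) == 1:
        return clades[0]
    k = int(rng.integers(1, len(clades)))
    order = rng.permutation(len(clades))
    node = TreeNode()
    for sub in ([clades[i] for i in order[:k]], [clades[i] for i in order[k:]]):
        if len(sub) == 1:
            child, child_height = sub[0]
        else:
            child_height = floor + (height - floor) * float(rng.uniform(0.3, 0.8))
            child, child_height = _join_clades(sub, child_height, floor, rng)
        child.length = height - child_height
        node.append(child)
    return node, height


def simulate_tree(config: SimConfig) -> tuple[TreeNode, dict[str, str]]:
    """Rooted binary tree with one clade per genomovar, plus leaf labels.

    Within-genomovar leaf pairs have path length at most
    2 * within_divergence (attained across each clade root); between-clade
    pairs at least 2 * between_divergence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    clades: list[tuple[TreeNode, float]] = []
    labels: dict[str, str] = {}
    for gv in range(config.n_genomovars):
        gv_name = f"gv{gv + 1}"
        leaves = [
            f"{gv_name}_g{j + 1}" for j in range(config.genomes_per_genomovar)
        ]
        for leaf in leaves:
            labels[leaf] = gv_name
        height = 0.0 if len(leaves) == 1 else config.within_divergence
        clade = _random_ultrametric(leaves, height, rng)
        clades.append((clade, height))
    if config.n_genomovars == 1:
        tree = clades[0][0]
        tree.length = None
    else:
        root_height = 1.2 * config.between_divergence
        tree, _ = _join_clades(clades, root_height, config.between_divergence, rng)
        tree.length = None
    _name_internal_nodes(tree)
    return tree, labels


def _name_internal_nodes(tree: TreeNode) -> None:
    counter = 0
    for node in tree.preorder():
        if not node.is_tip() and not node.name:
            counter += 1
            node.name = f"n{counter}"


# ---------------------------------------------------------------------------
# Gene-content simulation
# ---------------------------------------------------------------------------


def evolve_gene_content(
    tree: TreeNode, config: SimConfig
) -> tuple[PanMatrix, dict[str, tuple[int, int]]]:
    """Two-state Markov presence evolution for every family along the tree.

    The family universe is ``root_families`` (present at the root) plus
    ``accessory_pool`` (absent at the root).  On each branch every family
    runs a continuous-time jump process with rates gain_rate (0 -> 1) and
    loss_rate (1 -> 0); each realised jump is recorded, so per-branch event
    counts equal realised transitions exactly.  Marker-cluster families are
    handled separately by :func:`simulate` and are not part of this process.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n_universe = config.root_families + config.accessory_pool
    fam_ids = [f"fam{i + 1:05d}" for i in range(n_universe)]
    root_state = np.zeros(n_universe, dtype=bool)
    root_state[: config.root_families] = True

    states: dict[str, np.ndarray] = {tree.name: root_state}
    events: dict[str, tuple[int, int]] = {}
    for node in tree.preorder():
        if node is tree:
            continue
        parent_state = states[node.parent.name]
        child_state, gains, losses = _evolve_branch(
            parent_state, float(node.length or 0.0), config.gain_rate,
            config.loss_rate, rng,
        )
        states[node.name] = child_state
        events[node.name] = (gains, losses)

    tips = list(tree.tips()) or [tree]  # a one-genome tree is its own leaf
    leaf_sets = {
        leaf.name: {fam_ids[i] for i in np.flatnonzero(states[leaf.name])}
        for leaf in tips
    }
    # families never present in any leaf are unobservable and dropped
    observed = sorted(set().union(*leaf_sets.values()))
    if not observed:
        raise ValueError("simulation produced no observable families")
    pan = PanMatrix.from_family_sets(leaf_sets)
    return pan, events


def _evolve_branch(
    parent_state: np.ndarray, t: float, gain: float, loss: float, rng
) -> tuple[np.ndarray, int, int]:
    state = parent_state.copy()
    gains = losses = 0
    remaining = np.full(state.shape, t)
    active = np.ones(state.shape, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        rates = np.where(state[idx], loss, gain)
        dwell = np.full(idx.shape, np.inf)
        pos = rates > 0
        dwell[pos] = rng.exponential(1.0 / rates[pos])
        remaining[idx] -= dwell
        jumped = idx[remaining[idx] > 0]
        gains += int(np.sum(~state[jumped]))
        losses += int(np.sum(state[jumped]))
        state[jumped] = ~state[jumped]
        active[:] = False
        active[jumped] = True
    return state, gains, losses


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


def _random_cds(length: int, rng) -> np.ndarray:
    """Random CDS: ATG start, non-stop interior codons, TAA stop."""
    n_codons = length // 3
    codons = ["ATG"]
    picks = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2, p=_CODON_PROBS)
    codons.extend(_NONSTOP_CODONS[i] for i in picks)
    codons.append("TAA")
    seq = "".join(codons)
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_CODE = np.zeros(256, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: np.ndarray, t: float, rng) -> np.ndarray:
    """Jukes-Cantor substitutions over branch length t (subs/site).

    The final stop codon is frozen and any interior codon mutated into a
    stop is repaired (third base -> C) so translations stay full-length.
    """
    if t <= 0:
        return seq.copy()
    codes = _CODE[seq]
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    mutable = len(seq) - 3
    hit = np.flatnonzero(rng.random(mutable) < p)
    if hit.size == 0:
        return seq.copy()
    shift = rng.integers(1, 4, size=hit.size)
    codes = codes.copy()
    codes[hit] = (codes[hit] + shift) % 4
    out = _DECODE[codes]
    # repair interior stop codons introduced by mutation
    s = out.tobytes().decode()
    repaired = bytearray(out)
    for cs in range(0, mutable, 3):
        if s[cs : cs + 3] in _STOPS:
            repaired[cs + 2] = ord("C")
    return np.frombuffer(bytes(repaired), dtype=np.uint8)


def _translate(seq: np.ndarray) -> str:
    nt = seq.tobytes().decode()
    return str(Seq(nt[:-3]).translate())


def evolve_sequences(
    tree: TreeNode,
    pan: PanMatrix,
    config: SimConfig,
    cluster_presence: dict[str, list[str]] | None = None,
) -> tuple[list[GenomeRecord], dict[tuple[str, str], str]]:
    """Evolve one CDS per family along the tree and assemble genomes.

    Each family receives an independent random ancestral CDS at the root
    (fresh random sequences keep families unambiguous for clustering) and
    accumulates Jukes-Cantor substitutions down every branch.  Per genome,
    gene order is a seeded permutation; the marker cluster, when implanted,
    is inserted as one contiguous ordered block.

    Returns the genome records plus the truth mapping (genome, gene) -> family.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    families = list(pan.families)
    cluster_presence = cluster_presence or {}
    marker_fams = [m for m in MARKER_GENES if any(
        m in genes for genes in cluster_presence.values())]
    all_fams = families + marker_fams

    ancestral = {f: _random_cds(config.gene_length, rng) for f in all_fams}
    leaf_seqs: dict[str, dict[str, np.ndarray]] = {}

    def descend(node: TreeNode, seqs: dict[str, np.ndarray]) -> None:
        if node.is_tip():
            leaf_seqs[node.name] = seqs
            return
        for child in node.children:
            t = float(child.length or 0.0)
            child_seqs = {f: _mutate(s, t, rng) for f, s in seqs.items()}
            descend(child, child_seqs)

    descend(tree, ancestral)

    genomes: list[GenomeRecord] = []
    gene_families: dict[tuple[str, str], str] = {}
    for gi, genome_id in enumerate(pan.genomes):
        g_rng = np.random.default_rng(config.seed + 1000 + gi)
        fams_here = sorted(pan.family_set(genome_id))
        order = [fams_here[i] for i in g_rng.permutation(len(fams_here))]
        markers_here = cluster_presence.get(genome_id, [])
        if markers_here:
            insert_at = int(g_rng.integers(0, len(order) + 1))
            order = order[:insert_at] + list(markers_here) + order[insert_at:]
        strands = [
            "+" if (f in markers_here or g_rng.random() < 0.5) else "-"
            for f in order
        ]
        genome = _assemble_genome(
            genome_id, order, strands, leaf_seqs[genome_id], config, g_rng
        )
        for gene, fam in zip(genome.genes, order):
            gene_families[(genome_id, gene.gene_id)] = fam
        genomes.append(genome)
    return genomes, gene_families


def _random_spacer(length: int, rng) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _assemble_genome(
    genome_id: str,
    order: list[str],
    strands: list[str],
    seqs: dict[str, np.ndarray],
    config: SimConfig,
    rng,
) -> GenomeRecord:
    n_contigs = max(1, min(config.n_contigs, len(order)))
    bounds = np.array_split(np.arange(len(order)), n_contigs)
    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    gene_no = 0
    for ci, idxs in enumerate(bounds):
        parts: list[str] = []
        pos = 0
        cname = f"{genome_id}_ctg{ci + 1}"
        for i in idxs:
            fam = order[i]
            cds = seqs[fam].tobytes().decode()
            prot = _translate(seqs[fam])
            placed = cds if strands[i] == "+" else str(Seq(cds).reverse_complement())
            gene_no += 1
            start = pos + 1
            end = pos + len(placed)
            genes.append(
                Gene(
                    f"{genome_id}_{gene_no:04d}", cname, start, end, strands[i],
                    nucleotide=cds, protein=prot,
                )
            )
            parts.append(placed)
            pos = end
            spacer = _random_spacer(config.spacer_length, rng)
            parts.append(spacer)
            pos += len(spacer)
        contigs[cname] = "".join(parts)
    return GenomeRecord(genome_id, contigs, genes, declared_name=genome_id)


# ---------------------------------------------------------------------------
# Top-level simulation and (de)serialisation
# ---------------------------------------------------------------------------


def simulate(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: tree, gene content, sequences, marker cluster."""
    config.validate()
    tree, labels = simulate_tree(config)
    pan, events = evolve_gene_content(tree, config)

    cluster_presence: dict[str, list[str]] = {}
    cluster_status: dict[str, str] = {}
    for genome_id in pan.genomes:
        if not config.implant_cluster:
            cluster_presence[genome_id] = []
            cluster_status[genome_id] = "absent"
            continue
        present = [
            m for m in MARKER_GENES
            if not (genome_id in config.drop_cluster_gene_in and m == MARKER_GENES[0])
        ]
        cluster_presence[genome_id] = present
        cluster_status[genome_id] = "complete" if len(present) == len(MARKER_GENES) else "partial"

    genomes, gene_families = evolve_sequences(tree, pan, config, cluster_presence)
    genomes.sort(key=lambda g: g.genome_id)

    # the truth pan matrix includes implanted marker families
    if config.implant_cluster:
        full_sets = {
            gid: pan.family_set(gid) | set(cluster_presence[gid]) for gid in pan.genomes
        }
        pan_full = PanMatrix.from_family_sets(full_sets)
    else:
        pan_full = pan

    truth = TruthSet(tree, labels, pan_full, events, cluster_status)
    return SimulatedDataset(genomes, truth, config, gene_families)


def write_dataset(ds: SimulatedDataset, outdir: Path, overwrite: bool = False) -> None:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty; pass overwrite=True")
    for sub in ("genomes", "proteins", "annotations", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    for genome in ds.genomes:
        write_fasta(outdir / "genomes" / f"{genome.genome_id}.fna", genome.contigs)
        write_fasta(
            outdir / "proteins" / f"{genome.genome_id}.faa",
            {g.gene_id: g.protein for g in genome.genes_in_order()},
        )
        write_gff3(outdir / "annotations" / f"{genome.genome_id}.gff3", genome)
    truth = ds.truth
    (outdir / "truth" / "tree.nwk").write_text(newick(truth.true_tree) + "\n")
    pd.DataFrame(
        sorted(truth.true_genomovar_labels.items()), columns=["genome", "genomovar"]
    ).to_csv(outdir / "truth" / "labels.tsv", sep="\t", index=False)
    truth.true_pan_matrix.write_tsv(outdir / "truth" / "pan_matrix.tsv")
    pd.DataFrame(
        [(b, g, l) for b, (g, l) in sorted(truth.true_events.items())],
        columns=["branch", "gain_count", "loss_count"],
    ).to_csv(outdir / "truth" / "events.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_cluster_status.items()), columns=["genome", "status"]
    ).to_csv(outdir / "truth" / "cluster_status.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, gene, fam) for (g, gene), fam in sorted(ds.gene_families.items())],
        columns=["genome", "gene", "family"],
    ).to_csv(outdir / "truth" / "gene_families.tsv", sep="\t", index=False)
    (outdir / "sim_config.json").write_text(json.dumps(asdict(ds.config), indent=2))


def read_dataset(outdir: Path) -> SimulatedDataset:
    outdir = Path(outdir)
    config = SimConfig(**json.loads((outdir / "sim_config.json").read_text()))
    genomes = []
    for fna in sorted((outdir / "genomes").glob("*.fna")):
        gid = fna.stem
        genomes.append(
            read_genome(
                fna,
                outdir / "annotations" / f"{gid}.gff3",
                outdir / "proteins" / f"{gid}.faa",
                declared_name=gid,
            )
        )
    tree = TreeNode.read([(outdir / "truth" / "tree.nwk").read_text()])
    labels_df = pd.read_csv(outdir / "truth" / "labels.tsv", sep="\t")
    labels = dict(zip(labels_df.genome, labels_df.genomovar))
    pan = PanMatrix.read_tsv(outdir / "truth" / "pan_matrix.tsv")
    ev_df = pd.read_csv(outdir / "truth" / "events.tsv", sep="\t")
    events = {
        r.branch: (int(r.gain_count), int(r.loss_count)) for r in ev_df.itertuples()
    }
    st_df = pd.read_csv(outdir / "truth" / "cluster_status.tsv", sep="\t")
    status = dict(zip(st_df.genome, st_df.status))
    gf_df = pd.read_csv(outdir / "truth" / "gene_families.tsv", sep="\t")
    gene_families = {(r.genome, r.gene): r.family for r in gf_df.itertuples()}
    truth = TruthSet(tree, labels, pan, events, status)
    return SimulatedDataset(genomes, truth, config, gene_families)
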