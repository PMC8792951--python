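"""Distance trees, topology comparison, genomovar delineation, taxonomy report.

Trees are neighbour-joining trees on zero-diagonal matrices (100-ANI, the
GGDC intergenomic distance, or concatenated single-copy-core p-distance).
Topologies are compared with the Kendall-Colijn metric at lambda = 0
(root-to-MRCA edge counts for every leaf pair), with significance against
a random-topology background via a z-test.  Genomovars are the connected
components of the graph joining genome pairs that pass both the ANI and
dDDH cutoffs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .orthopan import HomologFamilies, cluster_homologs, single_copy_core
from .records import DistanceMatrix, GenomeRecord, as_skbio_distance

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a zero-diagonal distance matrix.

    Labels are sorted before agglomeration so ties break by label order;
    negative branch lengths are clamped to zero.  The result is unrooted
    (trifurcating top node).
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbour joining needs >= 3 genomes")
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    reordered = DistanceMatrix(
        [dm.labels[i] for i in order],
        dm.values[np.ix_(order, order)],
        dm.metric,
    )
    tree = _skbio_nj(as_skbio_distance(reordered))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def root_at_outgroup(tree: TreeNode, outgroup: list[str]) -> TreeNode:
    """Re-root on the branch leading to the outgroup leaves."""
    tips = {t.name for t in tree.tips()}
    missing = set(outgroup) - tips
    if missing:
        raise ValueError(f"outgroup leaves absent from tree: {sorted(missing)}")
    if len(outgroup) == 1:
        node = next(t for t in tree.tips() if t.name == outgroup[0])
    else:
        node = tree.lca(list(outgroup))
    rooted = tree.root_at(node.parent if node.is_tip() else node)
    return rooted


def root_at_midpoint(tree: TreeNode) -> TreeNode:
    return tree.root_at_midpoint()


def forms_clade(tree: TreeNode, leaves: set[str]) -> bool:
    """True when `leaves` is a split of the (possibly unrooted) tree."""
    all_tips = {t.name for t in tree.tips()}
    if not leaves <= all_tips:
        raise ValueError("leaves not in tree")
    complement = all_tips - leaves
    for node in tree.non_tips(include_self=True):
        sub = {t.name for t in node.tips()}
        if sub == leaves or sub == complement:
            return True
    return len(leaves) == 1 or not complement


# ---------------------------------------------------------------------------
# Concatenated single-copy-core distances
# ---------------------------------------------------------------------------


def core_gene_sequences(
    genomes: list[GenomeRecord],
    families: HomologFamilies,
    core_families: list[str] | None = None,
) -> dict[str, dict[str, str]]:
    """family -> {genome -> CDS nucleotide sequence} for single-copy core genes."""
    pan = families.to_pan_matrix([g.genome_id for g in genomes])
    core = core_families if core_families is not None else single_copy_core(pan)
    by_genome = {g.genome_id: {gene.gene_id: gene for gene in g.genes} for g in genomes}
    gene_map = families.gene_to_family()
    out: dict[str, dict[str, str]] = {f: {} for f in core}
    for (genome, gene), fam in gene_map.items():
        if fam in out and genome in by_genome:
            out[fam][genome] = by_genome[genome][gene].nucleotide
    return out


def concat_core_distance(core_seqs: dict[str, dict[str, str]]) -> DistanceMatrix:
    """Pairwise p-distance on the concatenation of single-copy core genes.

    Same-length family sequences are compared column-wise; length
    mismatches fall back to edit distance over the longer length.
    """
    if not core_seqs:
        raise ValueError(
            "no single-copy core families; dataset too sparse for a core phylogeny"
        )
    genomes = sorted(set.intersection(*(set(d) for d in core_seqs.values())))
    if len(genomes) < 2:
        raise ValueError("fewer than two genomes share all core families")
    n = len(genomes)
    mism = np.zeros((n, n))
    sites = np.zeros((n, n))
    for fam_seqs in core_seqs.values():
        arrs = {
            g: np.frombuffer(fam_seqs[g].encode(), dtype=np.uint8) for g in genomes
        }
        for i, j in itertools.combinations(range(n), 2):
            a, b = arrs[genomes[i]], arrs[genomes[j]]
            if len(a) == len(b):
                m = int(np.sum(a != b))
                s = len(a)
            else:
                m = edlib.align(
                    fam_seqs[genomes[i]], fam_seqs[genomes[j]],
                    mode="NW", task="distance",
                )["editDistance"]
                s = max(len(a), len(b))
            mism[i, j] += m
            mism[j, i] += m
            sites[i, j] += s
            sites[j, i] += s
    np.fill_diagonal(sites, 1.0)
    values = mism / sites
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(genomes, values, "p_distance")


# ---------------------------------------------------------------------------
# Kendall-Colijn topology comparison
# ---------------------------------------------------------------------------


def _ancestor_paths(tree: TreeNode) -> dict[str, list[TreeNode]]:
    paths: dict[str, list[TreeNode]] = {}

    def walk(node: TreeNode, trail: tuple[TreeNode, ...]) -> None:
        if node.is_tip():
            paths[node.name] = list(trail)
            return
        for child in node.children:
            walk(child, trail + (node,))

    walk(tree, ())
    return paths


def kc_vector(tree: TreeNode) -> np.ndarray:
    """Root-to-MRCA edge counts for all leaf pairs, leaves in sorted order."""
    paths = _ancestor_paths(tree)
    leaves = sorted(paths)
    vec = np.empty(len(leaves) * (len(leaves) - 1) // 2)
    for idx, (a, b) in enumerate(itertools.combinations(leaves, 2)):
        pa, pb = paths[a], paths[b]
        depth = 0
        for x, y in zip(pa, pb):
            if x is not y:
                break
            depth += 1
        vec[idx] = depth - 1  # edges from root to the MRCA
    return vec


def kc_distance(t1: TreeNode, t2: TreeNode, lam: float = 0.0) -> float:
    """Kendall-Colijn distance; lambda = 0 weighs topology only."""
    if lam != 0.0:
        raise NotImplementedError("only the topology-only (lambda = 0) form is provided")
    l1 = sorted(t.name for t in t1.tips())
    l2 = sorted(t.name for t in t2.tips())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return float(np.linalg.norm(kc_vector(t1) - kc_vector(t2)))


def random_rooted_tree(leaves: list[str], rng) -> TreeNode:
    """Uniform sequential random pair joining (Yule-like topology null)."""
    nodes = [TreeNode(name=name, length=1.0) for name in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=1.0)
        parent.append(nodes[i])
        parent.append(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    nodes[0].length = None
    return nodes[0]


@dataclass
class KCTestResult:
    distance: float
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    n_random: int


def kc_null_test(
    query: TreeNode, reference: TreeNode, n_random: int = 100000, seed: int = 0
) -> KCTestResult:
    """Is the query topology closer to the reference than random trees are?

    The background distribution is the KC distance from the query to
    `n_random` random rooted topologies over the same leaves; a one-sided
    z-test on the observed query-reference distance gives the p-value
    (small p: closer than expected by chance).
    """
    if n_random < 100:
        raise ValueError("n_random < 100 gives an unstable null")
    rng = np.random.default_rng(seed)
    leaves = sorted(t.name for t in query.tips())
    observed = kc_distance(query, reference)
    qvec = kc_vector(query)
    null = np.empty(n_random)
    for i in range(n_random):
        null[i] = float(np.linalg.norm(qvec - kc_vector(random_rooted_tree(leaves, rng))))
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null distribution")
    z = (observed - mean) / sd
    return KCTestResult(observed, mean, sd, z, float(stats.norm.cdf(z)), n_random)


# ---------------------------------------------------------------------------
# Genomovar delineation and taxonomy
# ---------------------------------------------------------------------------


@dataclass
class GenomovarAssignment:
    assignment: dict[str, str]
    ani_t: float
    ddh_t: float
    edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_genomovars(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, genomovar: str) -> list[str]:
        return sorted(g for g, gv in self.assignment.items() if gv == genomovar)


def delineate_genomovars(
    ani: DistanceMatrix,
    ddh: DistanceMatrix,
    ani_t: float = 94.5,
    ddh_t: float = 59.5,
) -> GenomovarAssignment:
    """Single-linkage genomovar delineation at joint ANI/dDDH cutoffs.

    Two genomes are linked when ANI >= ani_t and dDDH >= ddh_t; genomovars
    are the connected components, numbered by their smallest member label.
    The defaults sit just below the canonical ~95% ANI / ~60% dDDH marks
    so that borderline conspecific pairs (e.g. ANI 94.89 / dDDH 59.9)
    stay together.
    """
    if sorted(ani.labels) != sorted(ddh.labels):
        raise ValueError("ANI and dDDH matrices must share genome labels")
    graph = nx.Graph()
    graph.add_nodes_from(ani.labels)
    edges = []
    for a, b in itertools.combinations(sorted(ani.labels), 2):
        if ani[a, b] >= ani_t and ddh[a, b] >= ddh_t:
            graph.add_edge(a, b)
            edges.append((a, b))
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    assignment = {g: f"gv{i + 1}" for i, comp in enumerate(comps) for g in sorted(comp)}
    return GenomovarAssignment(assignment, ani_t, ddh_t, edges)


@dataclass
class TaxonomyReport:
    table: pd.DataFrame  # genome, declared, genomovar, reference_name, verdict
    counts: dict[str, int]


def taxonomy_report(
    assign: GenomovarAssignment,
    declared: dict[str, str],
    reference_names: dict[str, str],
) -> TaxonomyReport:
    """Compare declared names with genomovar-resolved reference names.

    Verdicts: ``consistent`` (declared matches the component's reference
    species), ``misidentified`` (conflict), ``newly_assigned`` (declared
    "sp." and now resolvable), ``novel_genomovar`` (component carries no
    reference name).
    """
    rows = []
    for genome, gv in sorted(assign.assignment.items()):
        name = declared.get(genome, "sp.")
        ref = reference_names.get(gv)
        if ref is None:
            verdict = "novel_genomovar"
        elif name in ("sp.", "", None):
            verdict = "newly_assigned"
        elif name == ref:
            verdict = "consistent"
        else:
            verdict = "misidentified"
        rows.append((genome, name, gv, ref or "", verdict))
    table = pd.DataFrame(
        rows, columns=["genome", "declared", "genomovar", "reference_name", "verdict"]
    )
    counts = table["verdict"].value_counts().to_dict()
    return TaxonomyReport(table, counts)


# ---------------------------------------------------------------------------
# Membership screening and summary statistics
# ---------------------------------------------------------------------------


def membership_screen(
    candidates: list[GenomeRecord],
    references: list[GenomeRecord],
    prefilter_ani: float = 80.0,
    ani_cfg=None,
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
) -> list[str]:
    """Screen candidate genomes for species-complex membership.

    A candidate is a member when (1) its best symmetrised ANI against the
    references reaches `prefilter_ani`, and (2) it falls inside the
    smallest clade containing all references in BOTH the 100-ANI
    neighbour-joining tree and the concatenated-core-distance tree
    (midpoint-rooted).
    """
    from .distances import build_matrix, fragment_ani

    if not references:
        raise ValueError("need at least one reference genome")
    ref_ids = [g.genome_id for g in references]
    retained = []
    for cand in candidates:
        best = 0.0
        for ref in references:
            res = fragment_ani(cand, ref, ani_cfg)
            if res.ani_percent is not None:  # unalignable pairs simply fail
                best = max(best, res.ani_percent)
        if best >= prefilter_ani:
            retained.append(cand)
    if not retained:
        return []
    pool = references + retained
    if len(pool) < 3:
        # too few genomes for trees; the ANI prefilter is the only signal
        return [c.genome_id for c in retained]
    keep = [g.genome_id for g in pool]
    ani_pool = build_matrix(pool, "ani", ani_cfg)
    trees = []
    trees.append(root_at_midpoint(nj_tree(ani_pool.transform("ani_dist"))))
    fams = cluster_homologs(
        {g.genome_id: g.proteome for g in pool}, min_identity, min_coverage
    )
    core_seqs = core_gene_sequences(pool, fams)
    core_seqs = {f: d for f, d in core_seqs.items() if set(d) >= set(keep)}
    trees.append(root_at_midpoint(nj_tree(concat_core_distance(core_seqs))))
    members = set(c.genome_id for c in retained)
    for tree in trees:
        clade = tree.lca(ref_ids) if len(ref_ids) > 1 else tree
        in_clade = {t.name for t in clade.tips()}
        members &= in_clade
    return sorted(members)


@dataclass
class GenomeStats:
    table: pd.DataFrame
    gc_test: tuple[float, float] | None  # Welch (t, p) on GC% between two groups


def genome_stats(
    genomes: list[GenomeRecord], groups: dict[str, str] | None = None
) -> GenomeStats:
    """Per-genome length/GC%/CDS table, with a Welch two-sample location
    test on GC% when `groups` names exactly two groups of >= 2 genomes."""
    rows = [
        (g.genome_id, g.length, g.gc_percent, len(g.genes)) for g in genomes
    ]
    table = pd.DataFrame(rows, columns=["genome", "length_bp", "gc_percent", "n_cds"])
    test = None
    if groups:
        table["group"] = [groups.get(g.genome_id, "") for g in genomes]
        names = [n for n in table["group"].unique() if n]
        if len(names) == 2:
            a = table.loc[table.group == names[0], "gc_percent"]
            b = table.loc[table.group == names[1], "gc_percent"]
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                test = (float(t), float(p))
            else:
                logger.warning("a group has < 2 genomes: no GC test performed")
    return GenomeStats(table, test)
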