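"""Homolog-family clustering, pan-genome matrix and frequency-category accounting.

Families are built from an all-vs-all protein similarity graph: a shared
k-mer prefilter proposes candidate pairs, pairwise alignment (edlib,
unit-cost edit distance) accepts an edge when identity and coverage clear
the configured thresholds, and families are the connected components of
the resulting graph.  This is a deterministic stand-in for graph-based
orthology tools; it is exact on well-separated synthetic families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .records import SELF_VALUES, DistanceMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("cloud", "shell", "softcore", "strict_core")


class PanMatrix:
    """Homolog-family x genome copy-count matrix.

    Rows are family ids, columns genome ids, entries per-genome gene
    counts.  ``presence()`` gives the collapsed presence/absence view used
    by categorisation, rarefaction and gain/loss inference.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.astype(int)
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("pan matrix has an empty family row")
        self.counts = counts

    @classmethod
    def from_family_sets(cls, family_sets: dict[str, set[str]]) -> "PanMatrix":
        """Build a presence (0/1) matrix from genome -> family-set mapping."""
        genomes = list(family_sets)
        fams = sorted(set().union(*family_sets.values())) if family_sets else []
        data = np.zeros((len(fams), len(genomes)), dtype=int)
        fam_idx = {f: i for i, f in enumerate(fams)}
        for j, g in enumerate(genomes):
            for f in family_sets[g]:
                data[fam_idx[f], j] = 1
        return cls(pd.DataFrame(data, index=fams, columns=genomes))

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genomes(self) -> int:
        return self.counts.shape[1]

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def family_set(self, genome: str) -> set[str]:
        col = self.counts[genome]
        return set(col.index[col > 0])

    def write_tsv(self, path: Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="family")

    @classmethod
    def read_tsv(cls, path: Path) -> "PanMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __eq__(self, other) -> bool:
        return isinstance(other, PanMatrix) and self.counts.sort_index().equals(
            other.counts.sort_index()
        )


@dataclass
class HomologFamilies:
    """Partition of all genes into homolog families."""

    members: dict[str, set[tuple[str, str]]]  # family id -> {(genome, gene)}
    representatives: dict[str, str] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.members)

    def gene_to_family(self) -> dict[tuple[str, str], str]:
        return {m: fid for fid, mem in self.members.items() for m in mem}

    def to_pan_matrix(self, genomes: list[str] | None = None) -> PanMatrix:
        if genomes is None:
            genomes = sorted({g for mem in self.members.values() for g, _ in mem})
        fams = sorted(self.members)
        data = np.zeros((len(fams), len(genomes)), dtype=int)
        gidx = {g: j for j, g in enumerate(genomes)}
        for i, f in enumerate(fams):
            for genome, _gene in self.members[f]:
                data[i, gidx[genome]] += 1
        return PanMatrix(pd.DataFrame(data, index=fams, columns=genomes))

    def write_tsv(self, path: Path) -> None:
        rows = [
            (fid, genome, gene)
            for fid in sorted(self.members)
            for genome, gene in sorted(self.members[fid])
        ]
        pd.DataFrame(rows, columns=["family", "genome", "gene"]).to_csv(
            path, sep="\t", index=False
        )


def protein_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage) of a global pairwise alignment.

    Identity is 1 - edit_distance / longer_length (a conservative lower
    bound on alignment-column identity); coverage is the shorter/longer
    length ratio, i.e. the fraction of the longer sequence the shorter one
    can possibly cover end to end.
    """
    if not a or not b:
        return 0.0, 0.0
    lo, hi = min(len(a), len(b)), max(len(a), len(b))
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / hi), lo / hi


def _kmer_candidate_pairs(
    seqs: list[str], k: int = 4, min_shared: int = 3
) -> list[tuple[int, int]]:
    """Sparse shared-k-mer counting; returns index pairs worth aligning."""
    kmer_ids: dict[str, int] = {}
    rows, cols = [], []
    for i, s in enumerate(seqs):
        words = {s[j : j + k] for j in range(len(s) - k + 1)}
        for w in words:
            rows.append(i)
            cols.append(kmer_ids.setdefault(w, len(kmer_ids)))
    if not kmer_ids:
        return []
    m = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(seqs), len(kmer_ids)),
    )
    shared = sparse.triu(m @ m.T, k=1).tocoo()
    return [(int(i), int(j)) for i, j, v in zip(shared.row, shared.col, shared.data) if v >= min_shared]


def cluster_homologs(
    proteomes: dict[str, dict[str, str]],
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
) -> HomologFamilies:
    """Cluster all proteins of all genomes into homolog families.

    Parameters
    ----------
    proteomes : mapping genome id -> {gene id -> protein sequence}
    min_identity, min_coverage : edge acceptance thresholds in (0, 1].

    Families are connected components; the family id is the
    lexicographically smallest ``genome|gene`` member, which makes ids
    independent of input order.
    """
    if not 0 < min_identity <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    keys: list[tuple[str, str]] = []
    seqs: list[str] = []
    for genome in sorted(proteomes):
        if not proteomes[genome]:
            logger.warning("proteome %s is empty", genome)
        for gene in sorted(proteomes[genome]):
            keys.append((genome, gene))
            seqs.append(proteomes[genome][gene])
    graph = nx.Graph()
    graph.add_nodes_from(range(len(keys)))
    for i, j in _kmer_candidate_pairs(seqs):
        ident, cov = protein_identity(seqs[i], seqs[j])
        if ident >= min_identity and cov >= min_coverage:
            graph.add_edge(i, j)
    members: dict[str, set[tuple[str, str]]] = {}
    reps: dict[str, str] = {}
    for comp in nx.connected_components(graph):
        named = sorted(comp, key=lambda i: f"{keys[i][0]}|{keys[i][1]}")
        fid = f"{keys[named[0]][0]}|{keys[named[0]][1]}"
        members[fid] = {keys[i] for i in comp}
        reps[fid] = seqs[named[0]]
    return HomologFamilies(members, reps)


@dataclass
class PanCategories:
    """Per-family frequency category with pan-genome-survey accounting.

    ``labels`` assigns each family exactly one of cloud / shell / softcore /
    strict_core.  In the reported totals the softcore bin subsumes the
    strict core, so pan size = cloud + shell + softcore(total).
    """

    labels: pd.Series
    softcore_frac: float
    cloud_max: int
    n_genomes: int

    @property
    def totals(self) -> dict[str, int]:
        c = self.labels.value_counts()
        strict = int(c.get("strict_core", 0))
        soft_only = int(c.get("softcore", 0))
        return {
            "strict_core": strict,
            "softcore": strict + soft_only,
            "shell": int(c.get("shell", 0)),
            "cloud": int(c.get("cloud", 0)),
            "pan": int(len(self.labels)),
        }

    def category_of(self, family: str) -> str:
        return str(self.labels.loc[family])


def categorize(
    pan: PanMatrix, softcore_frac: float = 0.95, cloud_max: int = 2
) -> PanCategories:
    """Bin families by occupancy k out of N genomes.

    cloud: k <= cloud_max; strict core: k = N; softcore: k > softcore_frac*N
    (strict core is the k = N subset of the softcore); shell: the rest.
    """
    n = pan.n_genomes
    if n < 3:
        logger.warning("fewer than 3 genomes: shell bin may be empty")
    k = pan.presence().sum(axis=1)
    labels = pd.Series("shell", index=pan.counts.index, dtype=object)
    labels[k <= cloud_max] = "cloud"
    labels[k > softcore_frac * n] = "softcore"
    labels[k == n] = "strict_core"
    return PanCategories(labels, softcore_frac, cloud_max, n)


def homolog_fraction(pan: PanMatrix) -> DistanceMatrix:
    """Shared-homolog percentage for every genome pair.

    value(i, j) = |families in both| / mean(|families in i|, |families in j|)
    * 100, computed on the presence view (per-genome paralogs collapsed);
    self-pairs are exactly 100.
    """
    pres = pan.presence().to_numpy().astype(int)
    n_fams = pres.sum(axis=0)
    if (n_fams == 0).any():
        empty = [g for g, c in zip(pan.genomes, n_fams) if c == 0]
        raise ValueError(f"genomes with zero families: {empty}")
    shared = pres.T @ pres
    mean_sizes = (n_fams[:, None] + n_fams[None, :]) / 2.0
    values = 100.0 * shared / mean_sizes
    np.fill_diagonal(values, SELF_VALUES["homolog_fraction"])
    return DistanceMatrix(pan.genomes, values, "homolog_fraction")


def single_copy_core(pan: PanMatrix) -> list[str]:
    """Families present exactly once in every genome."""
    mask = (pan.counts == 1).all(axis=1)
    fams = sorted(pan.counts.index[mask])
    if not fams:
        logger.warning("no single-copy core families: core phylogeny impossible")
    return fams
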