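"""Protein screening and ordered multi-gene cluster detection.

`protein_search` is a dependency-free local search: global pairwise
alignment against every protein in a proteome, with a Karlin-Altschul
style significance estimate for the +1/-1 scoring regime (lambda = ln 19
under uniform residue frequencies) corrected for database size.  The
`cluster_presence` operation automates the manual check for an ordered
gene cluster (the ectABCD-ask pattern): every query must hit a gene, the
hits must share one contig, and consecutive members may be separated by
at most `max_gap` intervening genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib

from .records import Gene, GenomeRecord

#: Karlin-Altschul parameters for +1 match / -1 mismatch scoring over a
#: 20-letter alphabet with uniform frequencies: sum p_i p_j e^(lambda*s) = 1
#: gives e^lambda = 19.
KA_LAMBDA = math.log(19.0)
KA_K = 0.1


@dataclass
class ScreenHit:
    genome: str
    gene_id: str
    identity: float  # percent
    coverage: float  # fraction of the query
    score: float
    significance: float


@dataclass
class ClusterCall:
    genome: str
    status: str  # complete | partial | absent
    found: list[str] = field(default_factory=list)  # query names, query order
    missing: list[str] = field(default_factory=list)
    anchor: str | None = None
    max_intervening: int = 0
    order_conserved: bool = True


def _alignment_stats(query: str, subject: str) -> tuple[float, float, float]:
    """(identity%, query coverage, score) of a global alignment."""
    hi = max(len(query), len(subject))
    dist = edlib.align(query, subject, mode="NW", task="distance")["editDistance"]
    identity = max(0.0, 1.0 - dist / hi)
    coverage = min(1.0, len(subject) / len(query))
    matches = hi - dist
    score = matches - dist  # +1 match / -1 mismatch-or-gap
    return 100.0 * identity, coverage, float(score)


def evalue(score: float, query_len: int, database_residues: int) -> float:
    """Extreme-value significance estimate E = K * m * n * exp(-lambda*S)."""
    log_e = math.log(KA_K) + math.log(max(query_len, 1)) + math.log(
        max(database_residues, 1)
    ) - KA_LAMBDA * score
    return math.exp(min(log_e, 700.0))


def protein_search(
    query: str,
    proteome: dict[str, str],
    genome: str = "",
    min_identity: float = 0.5,
    min_coverage: float = 0.7,
    max_significance: float = 1e-5,
) -> list[ScreenHit]:
    """Screen one query protein against a proteome.

    Hits must clear all three acceptance thresholds (significance,
    identity, query coverage); the list is sorted by score, best first.
    """
    if not query:
        raise ValueError("empty query protein")
    db_size = sum(len(s) for s in proteome.values())
    hits = []
    for gene_id, subject in proteome.items():
        if not subject:
            continue
        identity, coverage, score = _alignment_stats(query, subject)
        sig = evalue(score, len(query), db_size)
        if (
            sig <= max_significance
            and identity >= 100.0 * min_identity
            and coverage >= min_coverage
        ):
            hits.append(ScreenHit(genome, gene_id, identity, coverage, score, sig))
    return sorted(hits, key=lambda h: -h.score)


@dataclass
class Neighborhood:
    anchor: str
    genes: list[Gene]  # genomic order, anchor included
    truncated_left: bool
    truncated_right: bool


def neighborhood(genome: GenomeRecord, anchor_gene: str, flank: int = 20) -> Neighborhood:
    """Up to `flank` genes on each side of the anchor, in genomic order;
    truncation at contig ends is flagged."""
    ordered = genome.genes_in_order()
    idx = next((i for i, g in enumerate(ordered) if g.gene_id == anchor_gene), None)
    if idx is None:
        raise KeyError(f"anchor gene {anchor_gene!r} not found in {genome.genome_id}")
    contig = ordered[idx].contig
    same = [i for i, g in enumerate(ordered) if g.contig == contig]
    pos = same.index(idx)
    lo = max(0, pos - flank)
    hi = min(len(same), pos + flank + 1)
    genes = [ordered[i] for i in same[lo:hi]]
    return Neighborhood(
        anchor_gene,
        genes,
        truncated_left=(pos - lo) < flank,
        truncated_right=(hi - 1 - pos) < flank,
    )


def cluster_presence(
    genome: GenomeRecord,
    queries: dict[str, str],
    max_gap: int = 2,
    min_identity: float = 0.5,
    min_coverage: float = 0.7,
    max_significance: float = 1e-5,
) -> ClusterCall:
    """Call an ordered multi-gene cluster complete/partial/absent.

    Each query protein is searched in the genome; "complete" requires all
    queries to hit genes on a single contig with at most `max_gap`
    non-query genes between consecutive members.  Gene order within the
    cluster is reported (``order_conserved``) but not required for
    completeness.
    """
    if len(queries) < 2:
        raise ValueError("a cluster needs >= 2 query genes")
    proteome = genome.proteome
    best_hits: dict[str, str] = {}
    for qname, qseq in queries.items():
        hits = protein_search(
            qseq, proteome, genome.genome_id, min_identity, min_coverage,
            max_significance,
        )
        if hits:
            best_hits[qname] = hits[0].gene_id
    found = [q for q in queries if q in best_hits]
    missing = [q for q in queries if q not in best_hits]
    if not found:
        return ClusterCall(genome.genome_id, "absent", [], list(queries))
    anchor = best_hits[found[0]]
    ordered = genome.genes_in_order()
    index_of = {g.gene_id: i for i, g in enumerate(ordered)}
    positions = sorted(index_of[best_hits[q]] for q in found)
    contigs = {ordered[p].contig for p in positions}
    max_between = max(
        (b - a - 1 for a, b in zip(positions, positions[1:])), default=0
    )
    contiguous = len(contigs) == 1 and max_between <= max_gap
    complete = not missing and contiguous
    # order conformity: hit positions follow (or exactly reverse) query order
    hit_order = [index_of[best_hits[q]] for q in found]
    order_ok = hit_order == sorted(hit_order) or hit_order == sorted(hit_order)[::-1]
    status = "complete" if complete else "partial"
    return ClusterCall(
        genome.genome_id,
        status,
        found,
        missing,
        anchor=anchor,
        max_intervening=max_between,
        order_conserved=order_ok,
    )
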