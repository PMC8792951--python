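"""Pairwise whole-genome similarity metrics: fragment ANI, TETRA, digital DDH.

ANI follows the classical fragment definition: the query genome is cut
into fixed-length pieces (default 1,020 nt), each piece is placed on the
subject genome by exact k-mer seeding and aligned with edlib, and the mean
identity of the retained fragments is reported.  The digital-DDH estimate
mirrors the GGDC "formula 2" idea -- one minus summed identities over
summed HSP length, a quantity independent of total genome length -- and
is mapped to a dDDH percentage by a logistic curve anchored at
d=0 -> 99.9% and d=0.05 -> 60% (the observed ANI 95% <-> dDDH 60%
correspondence at genomovar scale).  TETRA is the Pearson correlation of
tetranucleotide z-score vectors under an order-2 Markov expectation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .records import SELF_VALUES, DistanceMatrix, GenomeRecord


@dataclass
class ANIConfig:
    fragment_length: int = 1020
    min_fragment_identity: float = 0.30
    min_fragment_coverage: float = 0.70
    seed_kmer: int = 15
    seed_step: int = 51  # spacing of query offsets probed for seeds

    def validate(self) -> None:
        if not 0 < self.min_fragment_identity <= 1:
            raise ValueError("min_fragment_identity must lie in (0, 1]")
        if not 0 < self.min_fragment_coverage <= 1:
            raise ValueError("min_fragment_coverage must lie in (0, 1]")
        if self.fragment_length < self.seed_kmer:
            raise ValueError("fragment_length must be >= seed_kmer")


@dataclass
class ANIResult:
    ani_percent: float | None
    aligned_fraction: float
    direction: str

    @property
    def aligned(self) -> bool:
        return self.ani_percent is not None


@dataclass
class TetraResult:
    r: float | None


@dataclass
class GGDCResult:
    d: float | None
    ddh_percent: float | None
    ci_halfwidth: float | None = None

    @property
    def aligned(self) -> bool:
        return self.d is not None


# dDDH logistic map: ddh(d) = 100 / (1 + exp(A + B*d)), pinned to the two
# anchors ddh(0) = 99.9 and ddh(0.05) = 60.  Closed-form coefficients.
DDH_ANCHORS = ((0.0, 99.9), (0.05, 60.0))


def _logistic_coefficients(anchors=DDH_ANCHORS) -> tuple[float, float]:
    (d0, y0), (d1, y1) = anchors
    a0 = math.log(100.0 / y0 - 1.0)
    a1 = math.log(100.0 / y1 - 1.0)
    b = (a1 - a0) / (d1 - d0)
    return a0 - b * d0, b


_DDH_A, _DDH_B = _logistic_coefficients()


def ddh_from_distance(d: float) -> float:
    """Map an intergenomic distance to a dDDH percentage (strictly decreasing)."""
    return 100.0 / (1.0 + math.exp(_DDH_A + _DDH_B * d))


# ---------------------------------------------------------------------------
# Fragment alignment machinery: exact k-mer seeds on both strands, then
# ungapped X-drop extension along the seeded diagonal (BLAST-style HSPs).
# ---------------------------------------------------------------------------

_NT_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
_RC = str.maketrans("ACGTN", "TGCAN")


class GenomeIndex:
    """Exact k-mer position index over both strands of a genome."""

    def __init__(self, genome: GenomeRecord, k: int):
        self.k = k
        fwd = "".join(genome.contigs[c] for c in sorted(genome.contigs)).upper()
        rev = fwd.translate(_RC)[::-1]
        self.strands = (fwd, rev)
        self.arrays = tuple(
            _NT_CODE[np.frombuffer(s.encode(), dtype=np.uint8)] for s in self.strands
        )
        index: dict[str, list[tuple[int, int]]] = {}
        for si, seq in enumerate(self.strands):
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((si, i))
        self.index = index


def _fragments(genome: GenomeRecord, length: int) -> list[str]:
    frags = []
    for name in sorted(genome.contigs):
        seq = genome.contigs[name].upper()
        for i in range(0, len(seq), length):
            frag = seq[i : i + length]
            if frag:
                frags.append(frag)
    return frags


def _xdrop_reach(step_scores: np.ndarray, x_drop: int) -> int:
    """Best-scoring prefix end under X-drop termination.

    `step_scores` are +1/-1 per column walking away from the seed; returns
    the number of columns to keep (maximising the running score, never
    walking past the point where it drops `x_drop` below its maximum).
    """
    if step_scores.size == 0:
        return 0
    run = np.cumsum(step_scores)
    peak = np.maximum.accumulate(run)
    dead = np.flatnonzero(peak - run > x_drop)
    limit = dead[0] if dead.size else step_scores.size
    if limit == 0:
        return 0
    best = int(np.argmax(run[:limit]))
    return best + 1 if run[best] > 0 else 0


def _best_hsp(
    frag_codes: np.ndarray, target: GenomeIndex, frag: str, cfg: ANIConfig,
    x_drop: int = 20,
) -> tuple[int, int] | None:
    """Best ungapped HSP (matches, length) of a fragment on the target."""
    seen: set[tuple[int, int]] = set()
    best: tuple[int, int] | None = None
    best_score = None
    n = len(frag)
    for off in range(0, max(1, n - cfg.seed_kmer + 1), cfg.seed_step):
        for si, pos in target.index.get(frag[off : off + cfg.seed_kmer], ())[:8]:
            diag = (si, pos - off)
            if diag in seen:
                continue
            seen.add(diag)
            tarr = target.arrays[si]
            shift = pos - off
            q_lo = max(0, -shift)
            q_hi = min(n, len(tarr) - shift)
            if q_hi - q_lo < cfg.seed_kmer:
                continue
            eq = frag_codes[q_lo:q_hi] == tarr[q_lo + shift : q_hi + shift]
            steps = np.where(eq, 1, -1).astype(np.int32)
            s0 = off - q_lo  # seed start within the window
            s1 = s0 + cfg.seed_kmer
            right = _xdrop_reach(steps[s1:], x_drop)
            left = _xdrop_reach(steps[:s0][::-1], x_drop)
            lo, hi = s0 - left, s1 + right
            matches = int(np.sum(eq[lo:hi]))
            length = hi - lo
            score = 2 * matches - length
            if best_score is None or score > best_score:
                best_score = score
                best = (matches, length)
    return best


def _pair_fragment_stats(
    query: GenomeRecord, subject: GenomeRecord, cfg: ANIConfig,
    index: GenomeIndex | None = None,
) -> tuple[list[float], int, int, int]:
    """One direction of the fragment screen.

    Returns (retained fragment identities, total fragments, pooled HSP
    matches, pooled HSP columns); retention follows the ANI
    identity/coverage filters while pooling (for the GGDC-style distance)
    only requires the identity floor.
    """
    if not query.contigs or not subject.contigs:
        raise ValueError("cannot align an empty genome")
    index = index or GenomeIndex(subject, cfg.seed_kmer)
    identities: list[float] = []
    matches_sum = columns_sum = 0
    frags = _fragments(query, cfg.fragment_length)
    for frag in frags:
        codes = _NT_CODE[np.frombuffer(frag.upper().encode(), dtype=np.uint8)]
        hit = _best_hsp(codes, index, frag.upper(), cfg)
        if hit is None:
            continue
        matches, length = hit
        if length == 0:
            continue
        identity = matches / length
        if identity < cfg.min_fragment_identity:
            continue
        matches_sum += matches
        columns_sum += length
        if length / len(frag) >= cfg.min_fragment_coverage:
            identities.append(identity)
    return identities, len(frags), matches_sum, columns_sum


def fragment_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    cfg: ANIConfig | None = None,
    _index_b: GenomeIndex | None = None,
    _index_a: GenomeIndex | None = None,
) -> ANIResult:
    """Symmetrised fragment ANI between two genomes.

    Each direction cuts one genome into fragments, aligns each to the
    other by seed-and-extend, keeps fragments passing the identity and
    coverage filters and averages their identities; the symmetrised value
    is the mean of both directions.  When no fragment aligns the result is
    an explicit no-alignment marker (``ani_percent = None``), never 0.
    """
    cfg = cfg or ANIConfig()
    cfg.validate()
    means, fracs = [], []
    for query, subject, idx in ((a, b, _index_b), (b, a, _index_a)):
        ids, n_frag, _, _ = _pair_fragment_stats(query, subject, cfg, idx)
        fracs.append(len(ids) / n_frag if n_frag else 0.0)
        if ids:
            means.append(100.0 * float(np.mean(ids)))
    mean = float(np.mean(means)) if means else None
    return ANIResult(mean, float(np.mean(fracs)), "symmetric")


def ggdc_distance(
    a: GenomeRecord,
    b: GenomeRecord,
    cfg: ANIConfig | None = None,
    _index_b: GenomeIndex | None = None,
    _index_a: GenomeIndex | None = None,
) -> GGDCResult:
    """Intergenomic distance d = 1 - sum(identities) / sum(HSP length).

    HSPs are the seeded fragment alignments pooled over both directions;
    d is a ratio over aligned columns only, hence independent of total
    genome length.  The dDDH percentage comes from the calibrated
    logistic map.
    """
    cfg = cfg or ANIConfig()
    cfg.validate()
    matches = columns = 0
    for query, subject, idx in ((a, b, _index_b), (b, a, _index_a)):
        _, _, m, c = _pair_fragment_stats(query, subject, cfg, idx)
        matches += m
        columns += c
    if columns == 0:
        return GGDCResult(None, None)
    d = 1.0 - matches / columns
    return GGDCResult(d, ddh_from_distance(d))


# ---------------------------------------------------------------------------
# TETRA
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _word_counts(seqs: list[str], k: int) -> np.ndarray:
    """Counts of all 4^k words over the sequences and their reverse
    complements; windows containing ambiguous bases are skipped."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    for seq in seqs:
        for s in (seq.upper(), seq.upper().translate(_COMPLEMENT)[::-1]):
            arr = code[np.frombuffer(s.encode(), dtype=np.uint8)]
            if len(arr) < k:
                continue
            valid = arr >= 0
            word = np.zeros(len(arr) - k + 1, dtype=np.int64)
            ok = np.ones(len(arr) - k + 1, dtype=bool)
            for j in range(k):
                word = word * 4 + np.where(valid[j : len(arr) - k + 1 + j],
                                           arr[j : len(arr) - k + 1 + j], 0)
                ok &= valid[j : len(arr) - k + 1 + j]
            np.add.at(counts, word[ok], 1)
    return counts


def tetra_zscores(genome: GenomeRecord) -> np.ndarray:
    """z-scores of the 256 tetranucleotides against the order-2 Markov
    expectation E[w1w2w3w4] = n(w1w2w3) * n(w2w3w4) / n(w2w3)."""
    if genome.length < 2000:
        raise ValueError("TETRA requires >= 2 kb of sequence")
    seqs = list(genome.contigs.values())
    c4 = _word_counts(seqs, 4)
    c3 = _word_counts(seqs, 3)
    c2 = _word_counts(seqs, 2)
    z = np.zeros(256)
    for w in range(256):
        left = w >> 2          # w1w2w3
        right = w & 0b111111   # w2w3w4
        mid = (w >> 2) & 0b1111  # w2w3
        if c3[left] == 0 or c3[right] == 0 or c2[mid] == 0:
            continue
        exp = c3[left] * c3[right] / c2[mid]
        if exp > 0:
            z[w] = (c4[w] - exp) / math.sqrt(exp)
    return z


def tetra_corr(a: GenomeRecord, b: GenomeRecord) -> TetraResult:
    """Pearson correlation of tetranucleotide z-score vectors.

    A genome whose word usage is degenerate (e.g. a single repeated base:
    almost every tetranucleotide unobserved, so the z-vector has no usable
    variance) yields an explicit undefined marker instead of a number.
    """
    za, zb = tetra_zscores(a), tetra_zscores(b)
    for z in (za, zb):
        if np.std(z) == 0 or np.count_nonzero(z) < 16:
            return TetraResult(None)
    return TetraResult(float(np.corrcoef(za, zb)[0, 1]))


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

METRICS = ("ani", "tetra", "ddh", "ani_dist", "ggdc_d")


def build_matrices(
    genomes: list[GenomeRecord], metrics: list[str], cfg: ANIConfig | None = None
) -> dict[str, DistanceMatrix]:
    """Symmetrised N x N matrices for several metrics in one pass.

    The alignment-based metrics (ani, ani_dist, ddh, ggdc_d) share a
    single fragment-alignment sweep per genome pair; ``ani_dist`` is the
    100 - ANI transform and ``ggdc_d`` the raw intergenomic distance
    underlying dDDH.  Diagonals carry each metric's exact self-value.
    """
    for metric in metrics:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    labels = [g.genome_id for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genome labels")
    cfg = cfg or ANIConfig()
    cfg.validate()
    n = len(genomes)
    need_align = any(m in ("ani", "ani_dist", "ddh", "ggdc_d") for m in metrics)
    need_tetra = "tetra" in metrics
    out = {m: np.zeros((n, n)) for m in metrics}
    indexes = [GenomeIndex(g, cfg.seed_kmer) for g in genomes] if need_align else None
    zs = [tetra_zscores(g) for g in genomes] if need_tetra else None
    for i, j in itertools.combinations(range(n), 2):
        if need_align:
            ids_f, nf_f, m_f, c_f = _pair_fragment_stats(
                genomes[i], genomes[j], cfg, indexes[j])
            ids_r, nf_r, m_r, c_r = _pair_fragment_stats(
                genomes[j], genomes[i], cfg, indexes[i])
            ids = ids_f + ids_r
            if (m_f + m_r) == 0 or not ids:
                raise ValueError(f"no alignment between {labels[i]} and {labels[j]}")
            means = []
            if ids_f:
                means.append(100.0 * float(np.mean(ids_f)))
            if ids_r:
                means.append(100.0 * float(np.mean(ids_r)))
            ani = float(np.mean(means))
            d = 1.0 - (m_f + m_r) / (c_f + c_r)
            vals = {"ani": ani, "ani_dist": 100.0 - ani, "ggdc_d": d,
                    "ddh": ddh_from_distance(d)}
        else:
            vals = {}
        if need_tetra:
            za, zb = zs[i], zs[j]
            vals["tetra"] = (
                float(np.corrcoef(za, zb)[0, 1])
                if np.std(za) > 0 and np.std(zb) > 0
                else np.nan
            )
        for metric in metrics:
            out[metric][i, j] = out[metric][j, i] = vals[metric]
    result = {}
    for metric in metrics:
        np.fill_diagonal(out[metric], SELF_VALUES[metric])
        result[metric] = DistanceMatrix(labels, out[metric], metric)
    return result


def build_matrix(
    genomes: list[GenomeRecord], metric: str, cfg: ANIConfig | None = None
) -> DistanceMatrix:
    """Full symmetrised N x N matrix of one metric over a genome set."""
    return build_matrices(genomes, [metric], cfg)[metric]
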