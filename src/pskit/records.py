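"""Shared data containers: genomes, genes and labelled pairwise matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Diagonal value each pairwise metric takes on a self-comparison.
SELF_VALUES = {
    "ani": 100.0,
    "ddh": 100.0,
    "tetra": 1.0,
    "ani_dist": 0.0,
    "ggdc_d": 0.0,
    "homolog_fraction": 100.0,
    "p_distance": 0.0,
}


@dataclass
class Gene:
    """A single CDS: 1-based inclusive coordinates on its contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    nucleotide: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates for {self.gene_id}: {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class GenomeRecord:
    """One genome: contigs, CDS annotations and the name it was deposited under."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    declared_name: str = ""

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def gc_percent(self) -> float:
        gc = at = 0
        for seq in self.contigs.values():
            up = seq.upper()
            gc += up.count("G") + up.count("C")
            at += up.count("A") + up.count("T")
        if gc + at == 0:
            raise ValueError(f"genome {self.genome_id} has no unambiguous bases")
        return 100.0 * gc / (gc + at)

    @property
    def proteome(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes if g.protein}

    def genes_in_order(self) -> list[Gene]:
        """Genes sorted by genomic position (contig name, then start)."""
        return sorted(self.genes, key=lambda g: (g.contig, g.start))

    def extract_cds(self, gene: Gene) -> str:
        seq = self.contigs[gene.contig][gene.start - 1 : gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


# ---------------------------------------------------------------------------
# FASTA / GFF3 round-trip helpers
# ---------------------------------------------------------------------------


def write_fasta(path: Path, entries: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in entries.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: Path, genome: GenomeRecord) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in genome.genes_in_order():
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig}\tpskit\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def read_gff3(path: Path) -> list[tuple[str, str, int, int, str]]:
    """Return (gene_id, contig, start, end, strand) tuples from a GFF3 file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            out.append((attrs["ID"], parts[0], int(parts[3]), int(parts[4]), parts[6]))
    return out


def read_genome(
    fna: Path, gff: Path | None = None, faa: Path | None = None, declared_name: str = ""
) -> GenomeRecord:
    """Assemble a :class:`GenomeRecord` from its on-disk representation."""
    fna = Path(fna)
    contigs = read_fasta(fna)
    genome = GenomeRecord(fna.stem, contigs, declared_name=declared_name)
    proteins = read_fasta(Path(faa)) if faa else {}
    if gff:
        for gene_id, contig, start, end, strand in read_gff3(Path(gff)):
            g = Gene(gene_id, contig, start, end, strand)
            g.nucleotide = genome.extract_cds(g)
            g.protein = proteins.get(gene_id, "")
            genome.genes.append(g)
    return genome


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labelled square matrix of a named pairwise genome metric.

    ``values[i, j]`` holds metric(labels[i], labels[j]); matrices built by
    :func:`pskit.distances.build_matrix` are symmetrised and carry the
    metric's exact self-value on the diagonal (ANI 100, TETRA 1, ...).
    """

    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate genome labels")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format export: N^2 rows including self-pairs and both orders."""
        rows = [
            (a, b, self.metric, self.values[i, j])
            for i, a in enumerate(self.labels)
            for j, b in enumerate(self.labels)
        ]
        return pd.DataFrame(rows, columns=["genome_a", "genome_b", "metric", "value"])

    def transform(self, metric: str) -> "DistanceMatrix":
        """Metric transforms used by the pipeline: ANI -> 100-ANI, dDDH -> GGDC d."""
        if self.metric == "ani" and metric == "ani_dist":
            return DistanceMatrix(list(self.labels), 100.0 - self.values, "ani_dist")
        raise ValueError(f"no transform {self.metric} -> {metric}")

    def write_tsv(self, path: Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="genome")

    @classmethod
    def read_tsv(cls, path: Path, metric: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), metric)


def as_skbio_distance(dm: DistanceMatrix):
    """Zero-diagonal matrix -> skbio DistanceMatrix (for neighbour joining)."""
    import skbio

    vals = np.array(dm.values, dtype=float)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return skbio.DistanceMatrix(vals, ids=dm.labels)
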