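"""Shared fixtures: small simulated species complexes and derived artifacts.

Everything is generated programmatically at session start; heavyweight
objects (alignment matrices, the end-to-end pipeline bundle) are computed
once and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from pskit import distances, orthopan
from pskit.pipeline import PipelineConfig, run_all
from pskit.records import GenomeRecord, write_fasta
from pskit.synthio import MARKER_GENES, SimConfig, simulate, write_dataset


def random_genome(genome_id: str, length: int, seed: int, n_contigs: int = 1) -> GenomeRecord:
    """Plain random genome (no genes) for distance-metric unit tests."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    per = length // n_contigs
    contigs = {
        f"{genome_id}_c{i + 1}": "".join(bases[rng.integers(0, 4, per)])
        for i in range(n_contigs)
    }
    return GenomeRecord(genome_id, contigs)


def mutate_genome(genome: GenomeRecord, frac: float, seed: int) -> GenomeRecord:
    """Substitute exactly round(frac * length) positions (no indels)."""
    rng = np.random.default_rng(seed)
    contigs = {}
    for name, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        code = {ord(b): i for i, b in enumerate("ACGT")}
        decode = np.frombuffer(b"ACGT", dtype=np.uint8)
        n_mut = int(round(frac * len(arr)))
        pos = rng.choice(len(arr), size=n_mut, replace=False)
        old = np.array([code[b] for b in arr[pos]])
        arr[pos] = decode[(old + rng.integers(1, 4, n_mut)) % 4]
        contigs[name] = arr.tobytes().decode()
    return GenomeRecord(genome_id=f"{genome.genome_id}_mut", contigs=contigs)


def diverged_relative(genome: GenomeRecord, frac: float, seed: int, new_id: str) -> GenomeRecord:
    """Uniformly substituted copy of an annotated genome (genes rebuilt),
    emulating a related species outside the complex."""
    from Bio.Seq import Seq

    from pskit.records import Gene

    mutated = mutate_genome(genome, frac, seed)
    contigs = dict(zip(genome.contigs, mutated.contigs.values()))
    out = GenomeRecord(new_id, contigs, declared_name=new_id)
    for g in genome.genes:
        ng = Gene(g.gene_id, g.contig, g.start, g.end, g.strand)
        ng.nucleotide = out.extract_cds(ng)
        ng.protein = str(Seq(ng.nucleotide[:-3]).translate())
        out.genes.append(ng)
    return out


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genomovars=3,
        genomes_per_genomovar=2,
        root_families=60,
        accessory_pool=40,
        seed=3,
        implant_cluster=True,
        drop_cluster_gene_in=["gv2_g1"],
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    return distances.build_matrices(
        small_dataset.genomes, ["ani", "ddh", "tetra", "ggdc_d"]
    )


@pytest.fixture(scope="session")
def small_families(small_dataset):
    return orthopan.cluster_homologs(small_dataset.proteomes())


@pytest.fixture(scope="session")
def marker_queries(small_dataset):
    g1 = small_dataset.genome("gv1_g1")
    inv = {
        fam: gene
        for (gid, gene), fam in small_dataset.gene_families.items()
        if gid == "gv1_g1"
    }
    return {m: g1.proteome[inv[m]] for m in MARKER_GENES}


# --- the end-to-end pipeline run, shared by pipeline and acceptance tests ---


@pytest.fixture(scope="session")
def complex_dataset():
    """Default-shape complex: 3 genomovars x 4 genomes, gain-heavy, with
    the marker cluster implanted and one genome lacking its first gene."""
    cfg = SimConfig(
        n_genomovars=3,
        genomes_per_genomovar=4,
        root_families=120,
        accessory_pool=80,
        seed=11,
        implant_cluster=True,
        drop_cluster_gene_in=["gv2_g1"],
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def complex_run(tmp_path_factory, complex_dataset):
    """run_all over the 12-genome complex, with one planted wrong label."""
    root = tmp_path_factory.mktemp("complex")
    write_dataset(complex_dataset, root / "data")
    g1 = complex_dataset.genome("gv1_g1")
    inv = {
        fam: gene
        for (gid, gene), fam in complex_dataset.gene_families.items()
        if gid == "gv1_g1"
    }
    write_fasta(root / "queries.faa", {m: g1.proteome[inv[m]] for m in MARKER_GENES})
    truth_labels = complex_dataset.truth.true_genomovar_labels
    species = {gv: f"P. synthetica_{gv}" for gv in sorted(set(truth_labels.values()))}
    declared = {g: species[truth_labels[g]] for g in truth_labels}
    declared["gv1_g3"] = species["gv2"]  # planted misidentification
    declared["gv3_g2"] = "sp."  # unnamed strain, resolvable
    reference_names = {f"{gv}_g1": species[gv] for gv in species}
    config = PipelineConfig(
        input_dir=str(root / "data"),
        output_dir=str(root / "out"),
        reference_names=reference_names,
        n_samples=500,
        kc_n_random=300,
        cluster_queries=str(root / "queries.faa"),
        seed=7,
    )
    bundle = run_all(config, declared=declared)
    return {
        "config": config,
        "bundle": bundle,
        "dataset": complex_dataset,
        "declared": declared,
        "root": root,
    }
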