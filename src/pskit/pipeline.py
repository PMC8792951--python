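"""End-to-end orchestration: distances -> delineation -> pan-genome ->
rarefaction -> trees -> gain/loss -> cluster screen, with seeded
reproducibility, per-stage content-hash caching and a consolidated report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusterscan, distances, gainloss, orthopan, rarefit, treekit
from .orthopan import PanCategories, PanMatrix
from .records import DistanceMatrix, GenomeRecord, read_fasta, read_genome

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    reference_names: dict[str, str] = field(default_factory=dict)  # genome -> species
    prefilter_ani: float = 80.0
    ani_t: float = 94.5
    ddh_t: float = 59.5
    min_identity: float = 0.5
    min_coverage: float = 0.5
    softcore_frac: float = 0.95
    cloud_max: int = 2
    n_samples: int = 20000
    posterior_threshold: float = 0.5
    optimization_rounds: int = 100
    kc_n_random: int = 1000
    screen_min_identity: float = 0.5
    screen_min_coverage: float = 0.7
    screen_max_significance: float = 1e-5
    cluster_queries: str = ""  # protein FASTA of ordered cluster queries
    max_gap: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def module_seed(self, name: str) -> int:
        """Deterministic per-module seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ReportBundle:
    genomovars: pd.DataFrame
    taxonomy: pd.DataFrame
    pan_accounting: dict
    range_table: pd.DataFrame
    pan_fit: rarefit.CurveFit
    core_fit: rarefit.CurveFit
    event_summary: dict
    cluster_calls: pd.DataFrame
    kc_tests: dict
    matrices: dict[str, DistanceMatrix]

    def validate(self) -> None:
        acc = self.pan_accounting
        counts = acc["counts"]
        if counts["cloud"] + counts["shell"] + counts["softcore"] != counts["pan"]:
            raise AssertionError("pan-genome category totals do not conserve")
        share = acc["percent"]
        total = share["cloud"] + share["shell"] + share["softcore"]
        if abs(total - 100.0) > 0.05:
            raise AssertionError(f"category percentages sum to {total}, not 100")

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genomovars.to_csv(outdir / "genomovars.tsv", sep="\t", index=False)
        self.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        self.range_table.to_csv(outdir / "genomovar_ranges.tsv", sep="\t", index=False)
        self.cluster_calls.to_csv(outdir / "cluster_calls.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(
                {
                    "pan_accounting": self.pan_accounting,
                    "pan_fit": {"params": self.pan_fit.params, "r2": self.pan_fit.r_squared,
                                "open": self.pan_fit.open_pan},
                    "core_fit": {"params": self.core_fit.params, "r2": self.core_fit.r_squared},
                    "events": self.event_summary,
                    "kc_tests": self.kc_tests,
                },
                fh,
                indent=2,
            )
        for name, dm in self.matrices.items():
            dm.write_tsv(outdir / f"matrix_{name}.tsv")
            dm.to_long().to_csv(outdir / f"matrix_{name}_long.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Accounting operations
# ---------------------------------------------------------------------------


def pan_accounting(categories: PanCategories, pan: PanMatrix | None = None) -> dict:
    """Category totals and shares in the conventional survey accounting.

    The softcore total subsumes the strict core, so
    pan = cloud + shell + softcore; "accessory" = shell + cloud.  Shares
    are reported raw and at the two printed precisions (two decimals and
    one decimal).
    """
    totals = categories.totals
    pan_size = totals["pan"]
    raw = {
        "strict_core": 100.0 * totals["strict_core"] / pan_size,
        "softcore": 100.0 * totals["softcore"] / pan_size,
        "shell": 100.0 * totals["shell"] / pan_size,
        "cloud": 100.0 * totals["cloud"] / pan_size,
        "accessory": 100.0 * (totals["shell"] + totals["cloud"]) / pan_size,
    }
    out = {
        "counts": totals,
        "percent": raw,
        "percent_2dp": {k: round(v, 2) for k, v in raw.items()},
        "percent_1dp": {k: round(v, 1) for k, v in raw.items()},
    }
    if pan is not None:
        comp = per_genome_composition(categories, pan)
        out["per_genome_mean"] = comp.mean().round(4).to_dict()
        out["per_genome_sd"] = comp.std(ddof=1).round(4).to_dict()
    return out


def per_genome_composition(categories: PanCategories, pan: PanMatrix) -> pd.DataFrame:
    """Per-genome percentage of softcore (incl. strict core), shell and
    cloud genes among that genome's families."""
    pres = pan.presence()
    labels = categories.labels
    soft = labels.isin(["softcore", "strict_core"])
    rows = {}
    for genome in pan.genomes:
        mask = pres[genome]
        n = int(mask.sum())
        rows[genome] = {
            "softcore": 100.0 * int((mask & soft).sum()) / n,
            "shell": 100.0 * int((mask & (labels == "shell")).sum()) / n,
            "cloud": 100.0 * int((mask & (labels == "cloud")).sum()) / n,
        }
    return pd.DataFrame(rows).T


def genomovar_range_table(
    ani: DistanceMatrix,
    ddh: DistanceMatrix,
    assignment: treekit.GenomovarAssignment,
    min_members: int = 3,
) -> pd.DataFrame:
    """Per-genomovar min/max ANI and dDDH over within-genomovar pairs.

    Only genomovars with at least `min_members` genomes are tabulated.
    """
    rows = []
    for gv in sorted(set(assignment.assignment.values()),
                     key=lambda s: int(s.lstrip("gv") or 0) if s.startswith("gv") else 0):
        members = assignment.members(gv)
        if len(members) < min_members:
            continue
        ani_vals = [ani[a, b] for i, a in enumerate(members) for b in members[i + 1:]]
        ddh_vals = [ddh[a, b] for i, a in enumerate(members) for b in members[i + 1:]]
        rows.append(
            (gv, len(members), min(ani_vals), max(ani_vals), min(ddh_vals), max(ddh_vals))
        )
    return pd.DataFrame(
        rows,
        columns=["genomovar", "n_genomes", "ani_min", "ani_max", "ddh_min", "ddh_max"],
    )


# ---------------------------------------------------------------------------
# Stage cache
# ---------------------------------------------------------------------------


class StageCache:
    """Content-hash stage cache: a stage whose key is unchanged is loaded
    from its previously written artifacts instead of recomputed."""

    def __init__(self, root: Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def key_path(self, stage: str) -> Path:
        return self.root / f"{stage}.key"

    def fresh(self, stage: str, key: str) -> bool:
        p = self.key_path(stage)
        return p.exists() and p.read_text() == key

    def commit(self, stage: str, key: str) -> None:
        self.key_path(stage).write_text(key)


def _hash_obj(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        h.update(json.dumps(part, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _hash_dir(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(path).rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def load_genomes(input_dir: Path) -> list[GenomeRecord]:
    input_dir = Path(input_dir)
    genomes = []
    for fna in sorted((input_dir / "genomes").glob("*.fna")):
        gid = fna.stem
        gff = input_dir / "annotations" / f"{gid}.gff3"
        faa = input_dir / "proteins" / f"{gid}.faa"
        genomes.append(
            read_genome(fna, gff if gff.exists() else None,
                        faa if faa.exists() else None, declared_name=gid)
        )
    if not genomes:
        raise FileNotFoundError(f"no genomes under {input_dir}/genomes")
    return genomes


def run_all(config: PipelineConfig, declared: dict[str, str] | None = None) -> ReportBundle:
    """Execute every stage in dependency order and assemble the report.

    `declared` overrides the declared species name per genome (defaults
    to each genome's own id).  Stage outputs land under
    ``config.output_dir``; a rerun with identical inputs and config reuses
    cached stage artifacts and reproduces the bundle byte-for-byte.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = StageCache(outdir / "stages")
    cfg_key = _hash_obj(asdict(config))
    input_key = _hash_dir(Path(config.input_dir))

    genomes = load_genomes(config.input_dir)
    declared = declared or {g.genome_id: g.declared_name for g in genomes}

    # --- distances ---------------------------------------------------------
    stage = "distances"
    key = _hash_obj(cfg_key, input_key, stage)
    matrices: dict[str, DistanceMatrix] = {}
    names = ("ani", "ddh", "tetra", "ggdc_d")
    if cache.fresh(stage, key):
        for name in names:
            matrices[name] = DistanceMatrix.read_tsv(
                outdir / "stages" / f"{name}.tsv", name)
        logger.info("stage %s: cache hit", stage)
    else:
        matrices = distances.build_matrices(genomes, list(names))
        for name in names:
            matrices[name].write_tsv(outdir / "stages" / f"{name}.tsv")
        cache.commit(stage, key)

    # --- genomovar delineation ---------------------------------------------
    assignment = treekit.delineate_genomovars(
        matrices["ani"], matrices["ddh"], config.ani_t, config.ddh_t
    )
    gv_ref_names: dict[str, str] = {}
    for genome, name in config.reference_names.items():
        if genome in assignment.assignment:
            gv_ref_names[assignment.assignment[genome]] = name
    report = treekit.taxonomy_report(assignment, declared, gv_ref_names)

    # --- pan-genome --------------------------------------------------------
    stage = "pan"
    key = _hash_obj(cfg_key, input_key, stage)
    pan_path = outdir / "stages" / "pan_matrix.tsv"
    if cache.fresh(stage, key):
        pan = PanMatrix.read_tsv(pan_path)
        logger.info("stage %s: cache hit", stage)
        families = None
    else:
        families = orthopan.cluster_homologs(
            {g.genome_id: g.proteome for g in genomes},
            config.min_identity, config.min_coverage,
        )
        pan = families.to_pan_matrix([g.genome_id for g in genomes])
        pan.write_tsv(pan_path)
        cache.commit(stage, key)
    categories = orthopan.categorize(pan, config.softcore_frac, config.cloud_max)
    accounting = pan_accounting(categories, pan)
    matrices["homolog_fraction"] = orthopan.homolog_fraction(pan)

    # --- rarefaction and fits ----------------------------------------------
    rar = rarefit.rarefy(pan, config.n_samples, config.module_seed("rarefy"))
    pan_fit, core_fit = rarefit.fit_curves(rar)
    rar.to_frame().to_csv(outdir / "stages" / "rarefaction.tsv", sep="\t", index=False)

    # --- trees --------------------------------------------------------------
    ani_tree = treekit.nj_tree(matrices["ani"].transform("ani_dist"))
    ggdc_tree = treekit.nj_tree(matrices["ggdc_d"])
    if families is None:
        families = orthopan.cluster_homologs(
            {g.genome_id: g.proteome for g in genomes},
            config.min_identity, config.min_coverage,
        )
    core_seqs = treekit.core_gene_sequences(genomes, families)
    core_tree = treekit.nj_tree(treekit.concat_core_distance(core_seqs))
    for name, tree in (("ani", ani_tree), ("ggdc", ggdc_tree), ("core", core_tree)):
        (outdir / "stages" / f"tree_{name}.nwk").write_text(str(tree))
    kc_tests = {}
    rooted = {
        name: treekit.root_at_midpoint(tree)
        for name, tree in (("ani", ani_tree), ("ggdc", ggdc_tree), ("core", core_tree))
    }
    for qname, rname in (("core", "ani"), ("core", "ggdc")):
        res = treekit.kc_null_test(
            rooted[qname], rooted[rname], config.kc_n_random,
            config.module_seed(f"kc:{qname}:{rname}"),
        )
        kc_tests[f"{qname}_vs_{rname}"] = {
            "distance": res.distance, "z": res.z, "p": res.p_value,
        }

    # --- gain/loss dynamics -------------------------------------------------
    event_tree = rooted["core"]
    model = gainloss.fit_rates(
        pan, event_tree, config.posterior_threshold, config.optimization_rounds
    )
    posteriors = gainloss.branch_posteriors(pan, event_tree, model)
    profile = gainloss.likely_events(posteriors, config.posterior_threshold, categories)
    profile.to_frame().to_csv(outdir / "stages" / "events.tsv", sep="\t", index=False)
    event_summary = {
        "gain_rate": model.gain_rate,
        "loss_rate": model.loss_rate,
        "root_prior": model.root_prior,
        "log_likelihood": model.log_likelihood,
        "total_likely_gains": profile.total_likely_gains,
        "total_likely_losses": profile.total_likely_losses,
        "gain_loss_ratio": profile.gain_loss_ratio,
    }

    # --- cluster screen ------------------------------------------------------
    calls = []
    if config.cluster_queries:
        queries = read_fasta(Path(config.cluster_queries))
        for genome in genomes:
            call = clusterscan.cluster_presence(
                genome, queries, config.max_gap, config.screen_min_identity,
                config.screen_min_coverage, config.screen_max_significance,
            )
            calls.append(
                (call.genome, call.status, ",".join(call.found),
                 ",".join(call.missing), call.order_conserved)
            )
    cluster_calls = pd.DataFrame(
        calls, columns=["genome", "status", "found", "missing", "order_conserved"]
    )

    gv_table = pd.DataFrame(
        sorted(assignment.assignment.items()), columns=["genome", "genomovar"]
    )
    bundle = ReportBundle(
        genomovars=gv_table,
        taxonomy=report.table,
        pan_accounting=accounting,
        range_table=genomovar_range_table(matrices["ani"], matrices["ddh"], assignment),
        pan_fit=pan_fit,
        core_fit=core_fit,
        event_summary=event_summary,
        cluster_calls=cluster_calls,
        kc_tests=kc_tests,
        matrices=matrices,
    )
    bundle.validate()
    bundle.write(outdir / "report")
    return bundle
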