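"""End-to-end orchestration: ingest/simulate -> QC -> diversity -> IBS/MDS
-> ROH -> HRR -> summaries -> islands -> gene annotation.

One structured config (YAML mapping or :class:`PipelineConfig`) drives the
whole workflow; every stage writes its table under the output directory and
a manifest records the config echo, dataset fingerprint and package
version.  Reruns with the same config and seed are byte-identical.

MDS runs on the LD-pruned marker set; run and island detection use the full
QC'd set (pruning is a structure-analysis step only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import (
    GenotypeDataset,
    LDPruneParams,
    QCParams,
    apply_qc,
    ld_prune,
    read_plink_text,
    write_plink_text,
)
from .islands import (
    GeneInterval,
    annotate_islands,
    call_islands,
    count_genes,
    islands_to_tsv,
    occurrence_threshold,
    read_gene_table,
    snp_occurrence,
)
from .popgen_stats import classical_mds, diversity_summary, ibs_matrix
from .runs_detection import RunParams, detect_runs
from .runs_summary import breed_summary, length_class_histogram, summarize_individuals
from .synthetic_data import SimConfig, TractSpec, simulate_dataset, write_truth_tsv

logger = logging.getLogger("snpruns")

__all__ = [
    "ConfigError",
    "IslandParams",
    "PipelineConfig",
    "PipelineArtifacts",
    "validate_config",
    "run_pipeline",
    "STAGES",
]

STAGES = (
    "ingest", "qc", "diversity", "mds", "roh", "hrr",
    "summaries", "islands", "report",
)


class ConfigError(ValueError):
    """Configuration schema violation, with the offending field path."""


@dataclass
class IslandParams:
    """Island-calling thresholds (top SNP fraction and frequency floors)."""

    top_fraction: float = 0.001
    min_freq_hom: float = 0.20
    min_freq_het: float = 0.30
    min_island_snps: int = 2


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of (ped/map paths, sim)."""

    out_dir: Path
    ped_path: Path | None = None
    map_path: Path | None = None
    sim: SimConfig | None = None
    qc: QCParams = field(default_factory=QCParams)
    ld: LDPruneParams = field(default_factory=LDPruneParams)
    roh: RunParams = field(default_factory=lambda: RunParams.for_mode("HOM"))
    hrr: RunParams = field(default_factory=lambda: RunParams.for_mode("HET"))
    islands: IslandParams = field(default_factory=IslandParams)
    genome_length_bp: float | None = None  # None -> SNP-covered span from data
    genes_path: Path | None = None
    genes_zero_based: bool = False
    mds_dims: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.ped_path is not None or self.map_path is not None
        if has_files == (self.sim is not None):
            raise ConfigError(
                "exactly one of (ped_path/map_path, sim) must be present"
            )
        if has_files and (self.ped_path is None or self.map_path is None):
            raise ConfigError("both ped_path and map_path are required")


@dataclass
class PipelineArtifacts:
    """Paths of every emitted table, keyed by artifact name."""

    paths: dict[str, Path]

    def __getitem__(self, key: str) -> Path:
        return self.paths[key]


def _build(cls, raw: dict, path: str, **extra):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**raw, **extra)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def validate_config(raw: dict) -> PipelineConfig:
    """Turn a raw (YAML-style) mapping into a validated PipelineConfig.

    Missing sections get the package defaults (QC 0.01 / 0.95 / 0.90;
    ROH 50-SNP window, 0 opposite, 0 missing, 1 Mb gap, 1 Mb minimum,
    50 SNPs, 1 SNP / 100 kb, proportion 0.05; HRR 15-SNP window / 100 kb;
    islands top 0.1% with >20% / >30% floors).  Unknown keys are rejected
    with their field path.
    """
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {
        "out_dir", "ped_path", "map_path", "sim", "qc", "ld", "roh", "hrr",
        "islands", "genome_length_bp", "genes_path", "genes_zero_based",
        "mds_dims", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ConfigError("out_dir: required")

    kwargs: dict = {
        "out_dir": Path(raw["out_dir"]),
        "genome_length_bp": raw.get("genome_length_bp"),
        "genes_zero_based": bool(raw.get("genes_zero_based", False)),
        "mds_dims": int(raw.get("mds_dims", 2)),
        "seed": int(raw.get("seed", 0)),
    }
    if raw.get("ped_path") is not None:
        kwargs["ped_path"] = Path(raw["ped_path"])
    if raw.get("map_path") is not None:
        kwargs["map_path"] = Path(raw["map_path"])
    if raw.get("genes_path") is not None:
        kwargs["genes_path"] = Path(raw["genes_path"])
    if raw.get("sim") is not None:
        sim_raw = dict(raw["sim"])
        tracts = [
            _build(TractSpec, dict(t), f"sim.tracts[{i}]")
            for i, t in enumerate(sim_raw.pop("tracts", []))
        ]
        if "allele_freq_range" in sim_raw:
            sim_raw["allele_freq_range"] = tuple(sim_raw["allele_freq_range"])
        sim_raw.setdefault("seed", kwargs["seed"])
        kwargs["sim"] = _build(SimConfig, sim_raw, "sim", tracts=tracts)
    if "qc" in raw:
        kwargs["qc"] = _build(QCParams, dict(raw["qc"]), "qc")
    if "ld" in raw:
        kwargs["ld"] = _build(LDPruneParams, dict(raw["ld"]), "ld")
    for key, mode in (("roh", "HOM"), ("hrr", "HET")):
        if key in raw:
            sub = dict(raw[key])
            sub.pop("mode", None)
            try:
                kwargs[key] = RunParams.for_mode(mode, **sub)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key}: {exc}") from exc
    if "islands" in raw:
        kwargs["islands"] = _build(IslandParams, dict(raw["islands"]), "islands")
    return PipelineConfig(**kwargs)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(
    cfg: PipelineConfig, through_stage: str = "report"
) -> PipelineArtifacts:
    """Execute the workflow up to ``through_stage`` (default: everything).

    Stage order: ingest (or simulate), qc, diversity, mds, roh, hrr,
    summaries, islands, report.  Every artifact lands in ``cfg.out_dir``;
    errors are reported with the failing stage's name.
    """
    if through_stage not in STAGES:
        raise ConfigError(f"unknown stage {through_stage!r}")
    last = STAGES.index(through_stage)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    paths["log"] = log_path

    try:
        # ingest ------------------------------------------------------------
        truths = []
        if cfg.sim is not None:
            ds, truths = simulate_dataset(cfg.sim)
            write_plink_text(ds, out / "simulated.ped", out / "simulated.map")
            write_truth_tsv(truths, out / "truth.tsv", seed=cfg.sim.seed)
            paths["ped"] = out / "simulated.ped"
            paths["map"] = out / "simulated.map"
            paths["truth"] = out / "truth.tsv"
            logger.info(
                "ingest: simulated %d samples x %d SNPs (seed %d)",
                ds.n_samples, ds.n_snps, cfg.sim.seed,
            )
        else:
            for p in (cfg.ped_path, cfg.map_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"[stage ingest] missing input file: {p}")
            ds = read_plink_text(cfg.ped_path, cfg.map_path)
            logger.info("ingest: read %d samples x %d SNPs", ds.n_samples, ds.n_snps)
        if last < STAGES.index("qc"):
            return PipelineArtifacts(paths)

        # qc ----------------------------------------------------------------
        try:
            ds, qc_report = apply_qc(ds, cfg.qc)
        except ValueError as exc:
            raise ValueError(f"[stage qc] {exc}") from exc
        qc_report.to_json(out / "qc_report.json")
        paths["qc_report"] = out / "qc_report.json"
        logger.info(
            "qc: %d->%d SNPs, %d->%d samples",
            qc_report.n_snps_in, qc_report.n_snps_out,
            qc_report.n_samples_in, qc_report.n_samples_out,
        )
        if last < STAGES.index("diversity"):
            return PipelineArtifacts(paths)

        # diversity ----------------------------------------------------------
        div = diversity_summary(ds)
        div.table.to_csv(out / "diversity.tsv", sep="\t", index=False,
                         float_format="%.6f")
        _write_json(out / "diversity.json",
                    div.table.to_dict(orient="records"))
        paths["diversity"] = out / "diversity.tsv"
        logger.info("diversity: %d breeds", len(div.table))
        if last < STAGES.index("mds"):
            return PipelineArtifacts(paths)

        # mds (LD prune -> IBS -> classical scaling) ---------------------------
        retained = ld_prune(ds, cfg.ld)
        (out / "pruned_snps.txt").write_text("\n".join(retained) + "\n")
        paths["pruned_snps"] = out / "pruned_snps.txt"
        keep = set(retained)
        snp_idx = np.array(
            [j for j, s in enumerate(ds.snps) if s.snp_id in keep], dtype=np.intp
        )
        pruned = ds.subset(snp_idx=snp_idx)
        dist = ibs_matrix(pruned)
        dist.to_tsv(out / "ibs_distance.tsv")
        paths["ibs_distance"] = out / "ibs_distance.tsv"
        mds = classical_mds(dist, k=min(cfg.mds_dims, ds.n_samples - 1))
        mds_df = mds.to_frame(breeds=[s.breed for s in ds.samples])
        mds_df.to_csv(out / "mds.tsv", sep="\t", index=False, float_format="%.8f")
        paths["mds"] = out / "mds.tsv"
        logger.info(
            "mds: pruned %d->%d SNPs, %d-dimension embedding",
            ds.n_snps, len(retained), mds.coords.shape[1],
        )
        if last < STAGES.index("roh"):
            return PipelineArtifacts(paths)

        # runs ----------------------------------------------------------------
        run_sets = {}
        for key, params, stage in (("roh", cfg.roh, "roh"), ("hrr", cfg.hrr, "hrr")):
            rs = detect_runs(ds, params)
            rs.to_tsv(out / f"runs_{key}.tsv")
            paths[f"runs_{key}"] = out / f"runs_{key}.tsv"
            run_sets[key] = rs
            logger.info("%s: %d runs", stage, len(rs))
            if last < STAGES.index(stage) + 1 and stage == through_stage:
                return PipelineArtifacts(paths)
        if last < STAGES.index("summaries"):
            return PipelineArtifacts(paths)

        # summaries -----------------------------------------------------------
        genome_len = (
            cfg.genome_length_bp
            if cfg.genome_length_bp is not None
            else ds.genome_length_bp()
        )
        for key in ("roh", "hrr"):
            indiv = summarize_individuals(run_sets[key], genome_len, ds=ds)
            pd.DataFrame([s.__dict__ for s in indiv]).to_csv(
                out / f"summary_individuals_{key}.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
            breeds = breed_summary(indiv)
            pd.DataFrame([b.__dict__ for b in breeds]).to_csv(
                out / f"summary_breeds_{key}.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
            hist = length_class_histogram(run_sets[key])
            hist.table.to_csv(
                out / f"length_classes_{key}.tsv", sep="\t", index=False
            )
            paths[f"summary_individuals_{key}"] = out / f"summary_individuals_{key}.tsv"
            paths[f"summary_breeds_{key}"] = out / f"summary_breeds_{key}.tsv"
            paths[f"length_classes_{key}"] = out / f"length_classes_{key}.tsv"
        logger.info("summaries: genome length %.0f bp", genome_len)
        if last < STAGES.index("islands"):
            return PipelineArtifacts(paths)

        # islands + annotation --------------------------------------------------
        genes: list[GeneInterval] = []
        if cfg.genes_path is not None:
            if not Path(cfg.genes_path).exists():
                raise FileNotFoundError(
                    f"[stage islands] missing gene table: {cfg.genes_path}"
                )
            genes = read_gene_table(cfg.genes_path, zero_based=cfg.genes_zero_based)
        gene_totals = {}
        for key, min_freq in (
            ("roh", cfg.islands.min_freq_hom),
            ("hrr", cfg.islands.min_freq_het),
        ):
            all_islands = []
            for breed in ds.breeds:
                track = snp_occurrence(run_sets[key], ds, breed)
                thr = occurrence_threshold(track, cfg.islands.top_fraction)
                all_islands.extend(
                    call_islands(
                        track, thr, min_freq,
                        min_island_snps=cfg.islands.min_island_snps,
                    )
                )
            report = annotate_islands(all_islands, genes)
            islands_to_tsv(report, out / f"islands_{key}.tsv")
            paths[f"islands_{key}"] = out / f"islands_{key}.tsv"
            total, unique = count_genes(report)
            gene_totals[key] = {
                "islands": len(all_islands), "genes_total": total,
                "genes_unique": unique,
            }
            logger.info(
                "islands(%s): %d islands, %d genes (%d unique)",
                key, len(all_islands), total, unique,
            )
        _write_json(out / "gene_report.json", gene_totals)
        paths["gene_report"] = out / "gene_report.json"
        if last < STAGES.index("report"):
            return PipelineArtifacts(paths)

        # manifest -------------------------------------------------------------
        manifest = {
            "version": __version__,
            "fingerprint": ds.fingerprint(),
            "seed": cfg.seed,
            "config": _config_echo(cfg),
        }
        _write_json(out / "manifest.json", manifest)
        paths["manifest"] = out / "manifest.json"
        logger.info("report: manifest written")
        return PipelineArtifacts(paths)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _config_echo(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)
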