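"""End-to-end orchestration: simulate -> qc -> abundance -> DE -> classify -> divergence.

A flat config (YAML mapping of scalars) drives the run; every threshold used
is echoed into the output manifest together with a sha256 hash of each
artifact, so a rerun with the same config can be checked for bit-identical
outputs.  The master seed fans out to per-stage seeds by hashing
``"{seed}:{stage}"`` (sha256, first 8 hex digits), so any stage rerun in
isolation with its derived seed reproduces the pipeline's result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import abundance as abundance_mod
from . import classify as classify_mod
from . import divergence as divergence_mod
from . import io_qc, pseudobulk, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "abundance", "de", "classify", "divergence")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (stable, documented rule)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16)


@dataclasses.dataclass
class PipelineConfig:
    """Flat pipeline configuration with explicit defaults."""

    # inputs: either simulate=True (SimConfig fields below) or paths
    simulate: bool = True
    counts_path: str | None = None
    metadata_path: str | None = None
    divergence_path: str | None = None
    # simulation block
    n_genes: int = 300
    n_cell_types: int = 3
    n_replicates_per_sex: int = 3
    cells_per_sample: int = 400
    type_proportions_female: list | None = None
    type_proportions_male: list | None = None
    nb_dispersion: float = 0.1
    libsize_logsd: float = 0.2
    dropout_rate: float = 0.0
    regulatory_fraction: float = 0.1
    regulatory_lfc: float = 3.0
    omega_unbiased: float = 0.15
    omega_biased: float = 0.5
    # QC
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 100
    qc_scope: str = "per_sample"  # or "merged"
    # thresholds
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    abundance_alpha: float = 0.01
    ds_max: float = 2.0
    # resampling
    bootstrap_B: int = 1000
    perm_B: int = 1000
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if not (0 < cfg.fdr_threshold < 1 and 0 < cfg.abundance_alpha < 1):
            raise ValueError("fdr_threshold and abundance_alpha must lie in (0, 1)")
        if cfg.lfc_threshold < 0 or cfg.ds_max < 0:
            raise ValueError("lfc_threshold and ds_max must be >= 0")
        if min(cfg.bootstrap_B, cfg.perm_B) < 1:
            raise ValueError("resampling replicate counts must be >= 1")
        if cfg.qc_scope not in ("per_sample", "merged"):
            raise ValueError("qc_scope must be 'per_sample' or 'merged'")
        if not cfg.simulate and (cfg.counts_path is None or cfg.metadata_path is None):
            raise ValueError("counts_path and metadata_path required when simulate=false")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(
            n_genes=self.n_genes,
            n_cell_types=self.n_cell_types,
            n_replicates_per_sex=self.n_replicates_per_sex,
            cells_per_sample=self.cells_per_sample,
            type_proportions_female=self.type_proportions_female,
            type_proportions_male=self.type_proportions_male,
            nb_dispersion=self.nb_dispersion,
            libsize_logsd=self.libsize_logsd,
            dropout_rate=self.dropout_rate,
            regulatory_fraction=self.regulatory_fraction,
            regulatory_lfc=self.regulatory_lfc,
            omega_by_group={
                "unbiased": self.omega_unbiased,
                "biased": self.omega_biased,
            },
            lfc_threshold=self.lfc_threshold,
            seed=stage_seed(self.seed, "simulate"),
        )


def demo_config(outdir: str = "results", seed: int = 0) -> PipelineConfig:
    """Small end-to-end demonstration: one abundance-shifted cell type plus
    regulatory effects, completing in well under a minute."""
    return PipelineConfig(
        simulate=True,
        n_genes=300,
        n_cell_types=3,
        n_replicates_per_sex=3,
        cells_per_sample=400,
        type_proportions_female=[0.5, 0.25, 0.25],
        type_proportions_male=[0.25, 0.375, 0.375],
        regulatory_fraction=0.1,
        regulatory_lfc=3.0,
        min_genes_per_cell=10,
        bootstrap_B=200,
        perm_B=200,
        seed=seed,
        outdir=outdir,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    artifacts: list[str] = []
    manifest: dict[str, Any] = {"config": config.to_dict(), "stages": {}}

    def emit(stage: str, name: str, df: pd.DataFrame) -> None:
        path = os.path.join(outdir, name)
        _write_tsv(df, path)
        artifacts.append(path)
        manifest["stages"].setdefault(stage, []).append(name)

    # -- simulate ----------------------------------------------------------
    truth = None
    div_table = None
    try:
        if config.simulate:
            sim_cfg = config.sim_config()
            counts, meta, truth = simulate.simulate_counts(sim_cfg)
            sim_dir = os.path.join(outdir, "sim")
            simulate.write_simulation(sim_dir, counts, meta, truth, sim_cfg)
            for rel in ("counts/matrix.mtx", "counts/features.tsv",
                        "counts/barcodes.tsv", "metadata.tsv", "truth.tsv",
                        "sim_config.txt"):
                artifacts.append(os.path.join(sim_dir, rel))
            manifest["stages"]["simulate"] = ["sim/"]
            div_table = simulate.simulate_divergence(sim_cfg)
        else:
            counts = io_qc.read_counts(config.counts_path)
            # structural validation of the metadata belongs to the qc stage
            meta = pd.read_csv(config.metadata_path, sep="\t", dtype=str)
            if config.divergence_path:
                div_table = divergence_mod.read_divergence(config.divergence_path)
    except Exception as exc:
        raise StageError("simulate" if config.simulate else "load", exc) from exc

    # -- qc ----------------------------------------------------------------
    try:
        if isinstance(meta, pd.DataFrame):
            meta = io_qc.CellMetadata(meta)
        meta = meta.aligned_to(counts)
        if config.qc_scope == "per_sample":
            counts, meta = io_qc.filter_counts_per_sample(
                counts, meta, config.min_cells_per_gene, config.min_genes_per_cell
            )
        else:
            counts = io_qc.filter_counts(
                counts, config.min_cells_per_gene, config.min_genes_per_cell
            )
            meta = meta.subset_cells(counts.cell_ids).aligned_to(counts)
        qc_table = io_qc.depth_correlation(counts, meta)
        emit("qc", "qc_depth_correlation.tsv", qc_table)
    except Exception as exc:
        raise StageError("qc", exc) from exc

    # -- abundance ---------------------------------------------------------
    try:
        ab = abundance_mod.test_abundance(meta, alpha=config.abundance_alpha)
        emit("abundance", "abundance.tsv", ab)
        emit("abundance", "abundance_replicates.tsv",
             abundance_mod.replicate_proportions(meta))
    except Exception as exc:
        raise StageError("abundance", exc) from exc

    # -- de ----------------------------------------------------------------
    de_by_stratum: dict[str, pd.DataFrame] = {}
    skipped: dict[str, str] = {}
    try:
        strata = [pseudobulk.WHOLE_TISSUE] + sorted(
            meta.frame["cell_type"].unique()
        )
        for stratum in strata:
            pb = pseudobulk.aggregate(counts, meta, stratum)
            tag = "bulk" if stratum == pseudobulk.WHOLE_TISSUE else stratum
            emit("de", f"pseudobulk_{tag}.tsv",
                 pb.to_frame().reset_index(names="gene_id"))
            try:
                res = pseudobulk.nb_de_test(
                    pb, config.lfc_threshold, config.fdr_threshold
                )
            except pseudobulk.StratumError as exc:
                skipped[stratum] = str(exc)
                logger.warning("%s", exc)
                continue
            de_by_stratum[stratum] = res
            emit("de", f"de_{tag}.tsv", res)
        if pseudobulk.WHOLE_TISSUE not in de_by_stratum:
            raise RuntimeError("whole-tissue stratum could not be tested")
        manifest["stages"].setdefault("de", [])
        manifest["de_skipped_strata"] = skipped
    except StageError:
        raise
    except Exception as exc:
        raise StageError("de", exc) from exc

    # -- classify ----------------------------------------------------------
    try:
        bulk_res = de_by_stratum[pseudobulk.WHOLE_TISSUE]
        per_type = {
            k: v for k, v in de_by_stratum.items() if k != pseudobulk.WHOLE_TISSUE
        }
        cats = classify_mod.classify_genes(bulk_res, per_type)
        emit("classify", "categories.tsv", cats)
        summary = classify_mod.summarize_categories(cats)
        with open(os.path.join(outdir, "category_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        artifacts.append(os.path.join(outdir, "category_summary.json"))
        manifest["stages"]["classify"] = ["categories.tsv", "category_summary.json"]
    except Exception as exc:
        raise StageError("classify", exc) from exc

    # -- divergence --------------------------------------------------------
    try:
        if div_table is not None:
            table = divergence_mod.compare_categories(
                cats,
                div_table,
                bootstrap_B=config.bootstrap_B,
                perm_B=config.perm_B,
                seed=stage_seed(config.seed, "divergence"),
                ds_max=config.ds_max,
            )
            emit("divergence", "divergence_groups.tsv", table)
            with open(os.path.join(outdir, "divergence_pairwise.json"), "w") as fh:
                json.dump(table.attrs.get("pairwise_p", {}), fh, indent=2, sort_keys=True)
            artifacts.append(os.path.join(outdir, "divergence_pairwise.json"))
            manifest["stages"]["divergence"].append("divergence_pairwise.json")
        else:
            manifest["stages"]["divergence"] = []
    except Exception as exc:
        raise StageError("divergence", exc) from exc

    manifest["hashes"] = {
        os.path.relpath(p, outdir): _sha256(p) for p in sorted(artifacts)
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(artifact_dir: str) -> str:
    """Assemble a human-readable summary from a completed run's artifacts."""
    manifest_path = os.path.join(artifact_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"no manifest.json in {artifact_dir!r}")
    lines = ["== pipeline report =="]

    def maybe(path):
        full = os.path.join(artifact_dir, path)
        return pd.read_csv(full, sep="\t") if os.path.exists(full) else None

    ab = maybe("abundance.tsv")
    if ab is not None:
        lines.append("\n-- differential cell-type abundance --")
        lines.append(ab.to_string(index=False))
    else:
        lines.append("\n[notice] abundance output missing")

    cats = maybe("categories.tsv")
    if cats is not None:
        summary = classify_mod.summarize_categories(cats)
        lines.append("\n-- gene categories --")
        for k, v in summary["counts"].items():
            lines.append(f"{k:>15}: {v}")
        lines.append(f"cell-level union: {summary['cell_level_union']}")
        lines.append(f"bulk-level union: {summary['bulk_level_union']}")
        lines.append(f"cell-only fraction: {summary['cell_only_fraction']:.3g}")
    else:
        lines.append("\n[notice] classification output missing")

    div = maybe("divergence_groups.tsv")
    if div is not None:
        lines.append("\n-- divergence by group --")
        lines.append(div.to_string(index=False))
    else:
        lines.append("\n[notice] divergence output missing")
    return "\n".join(lines)
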