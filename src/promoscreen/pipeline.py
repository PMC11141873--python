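"""End-to-end orchestration of the promoter motif screen.

Stages, in order: detection filter -> log-CPM transform -> seed-gene
Spearman screen -> correlated-set selection -> promoter window
extraction (per window spec) -> motif scanning -> logistic-GAM
enrichment with BH-FDR per window family -> motif target ranking.
Every intermediate is materialised as TSV/BED so any stage can be
inspected or unit-tested in isolation; a JSON manifest records the
config hash, seed, versions and row counts at each stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .correlation import SelectionPolicy, select_correlated_set, spearman_screen
from .enrichment import run_motif_screen
from .expression import DetectionFilterConfig, detection_filter, load_count_matrix, log_cpm_transform
from .motifs import count_motif_sites, read_motif_library
from .promoters import (
    extract_sequence,
    gc_content,
    read_annotation_bed6,
    read_annotation_gff3,
    upstream_window,
    windows_to_bed,
)

log = logging.getLogger("promoscreen")


class ConfigError(ValueError):
    """Pipeline configuration is invalid; names the offending key."""


@dataclass
class PipelineConfig:
    counts: str = ""
    lengths: str = ""
    genome: str = ""
    annotation: str = ""
    motifs: str = ""
    outdir: str = "results"
    seed_gene_id: str = ""
    # (upstream_bp, downstream_bp) pairs; defaults mirror a multi-window
    # promoter screen with 1 kb downstream added to the widest window
    windows: list[tuple[int, int]] = field(
        default_factory=lambda: [(1000, 0), (2000, 0), (5000, 0), (10000, 1000)]
    )
    filter: DetectionFilterConfig = field(default_factory=DetectionFilterConfig)
    correlation_policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    predictor: str = "log1p_count"
    basis_dim: int = 5
    min_sites: int = 5
    gam_alpha: float = 1.0
    top_n_targets: int = 12
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        paths = raw.get("paths", {})
        for key in ("counts", "lengths", "genome", "annotation", "motifs"):
            if key in paths:
                setattr(cfg, key, paths[key])
        cfg.outdir = raw.get("outdir", cfg.outdir)
        cfg.seed_gene_id = raw.get("seed_gene_id", cfg.seed_gene_id)
        if "windows" in raw:
            cfg.windows = [tuple(int(v) for v in w) for w in raw["windows"]]
        if "filter" in raw:
            cfg.filter = DetectionFilterConfig(**raw["filter"])
        if "correlation" in raw:
            cfg.correlation_policy = SelectionPolicy(**raw["correlation"])
        enr = raw.get("enrichment", {})
        cfg.predictor = enr.get("predictor", cfg.predictor)
        cfg.basis_dim = int(enr.get("basis_dim", cfg.basis_dim))
        cfg.min_sites = int(enr.get("min_sites", cfg.min_sites))
        cfg.gam_alpha = float(enr.get("alpha", cfg.gam_alpha))
        tgt = raw.get("targets", {})
        cfg.top_n_targets = int(tgt.get("top_n", cfg.top_n_targets))
        cfg.rng_seed = int(raw.get("rng_seed", cfg.rng_seed))
        return cfg

    def to_dict(self) -> dict:
        return {
            "paths": {
                "counts": self.counts, "lengths": self.lengths,
                "genome": self.genome, "annotation": self.annotation,
                "motifs": self.motifs,
            },
            "outdir": self.outdir,
            "seed_gene_id": self.seed_gene_id,
            "windows": [list(w) for w in self.windows],
            "filter": {
                "cpm_threshold": self.filter.cpm_threshold,
                "min_sample_fraction": self.filter.min_sample_fraction,
                "ci_level": self.filter.ci_level,
            },
            "correlation": {
                "rho_min": self.correlation_policy.rho_min,
                "fdr_max": self.correlation_policy.fdr_max,
                "top_n": self.correlation_policy.top_n,
                "sign": self.correlation_policy.sign,
            },
            "enrichment": {
                "predictor": self.predictor, "basis_dim": self.basis_dim,
                "min_sites": self.min_sites, "alpha": self.gam_alpha,
            },
            "targets": {"top_n": self.top_n_targets},
            "rng_seed": self.rng_seed,
        }

    def validate(self) -> None:
        for key in ("counts", "lengths", "genome", "annotation", "motifs"):
            path = getattr(self, key)
            if not path:
                raise ConfigError(f"config key paths.{key} is missing")
            if not os.path.exists(path):
                raise ConfigError(f"config key paths.{key}: no such file {path!r}")
        if not self.seed_gene_id:
            raise ConfigError("config key seed_gene_id is missing")
        if not self.windows:
            raise ConfigError("config key windows must be non-empty")

    def content_hash(self) -> str:
        # hash the analytic parameters only: file locations say nothing
        # about what was computed, and identical inputs at different
        # paths must yield identical outputs
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("paths", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_header(cfg: PipelineConfig) -> str:
    return f"# promoscreen {__version__} config={cfg.content_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: str, cfg: PipelineConfig, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg))
        df.to_csv(fh, sep="\t", index=index)


def load_annotation(path):
    if str(path).endswith((".gff", ".gff3")):
        return read_annotation_gff3(path)
    return read_annotation_bed6(path)


def run_screen(cfg: PipelineConfig) -> dict:
    """Run the full screen; returns the manifest dictionary.

    Stage errors propagate (with the stage name in the manifest); the
    manifest is written even on failure, and TSVs already produced are
    retained.
    """
    from pyfaidx import Fasta

    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "tool": "promoscreen",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "rng_seed": cfg.rng_seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "status": "running",
    }
    stage = "init"
    t0 = time.time()
    try:
        stage = "load"
        cm = load_count_matrix(cfg.counts, cfg.lengths)
        manifest["stages"]["load"] = {
            "n_genes": len(cm.gene_ids), "n_samples": len(cm.sample_ids)
        }

        stage = "detection_filter"
        filtered, report = detection_filter(cm, cfg.filter)
        _write_tsv(
            report.table, os.path.join(cfg.outdir, "detection_report.tsv"), cfg, True
        )
        manifest["stages"]["detection_filter"] = {
            "n_kept": int(report.table["kept"].sum()),
            "min_qualifying": report.min_qualifying,
        }
        log.info("detection filter kept %d genes", int(report.table["kept"].sum()))

        stage = "transform"
        expr = log_cpm_transform(filtered)

        stage = "correlation"
        corr = spearman_screen(expr, cfg.seed_gene_id)
        gene_set = select_correlated_set(corr, cfg.seed_gene_id, cfg.correlation_policy)
        corr_out = corr.copy()
        corr_out["selected"] = corr_out.index.isin(gene_set.member_gene_ids).astype(int)
        _write_tsv(corr_out, os.path.join(cfg.outdir, "correlation.tsv"), cfg, True)
        manifest["stages"]["correlation"] = {
            "n_tested": len(corr),
            "n_selected": len(gene_set.member_gene_ids),
            "selection_rule": gene_set.selection_rule,
        }
        log.info("selected %d correlated genes", len(gene_set.member_gene_ids))

        stage = "promoters"
        genome = Fasta(cfg.genome)
        contig_len = {name: len(genome[name]) for name in genome.keys()}
        annotations = [
            a for a in load_annotation(cfg.annotation) if a.gene_id in expr.values.index
        ]
        library = read_motif_library(cfg.motifs)
        membership_universe = [a.gene_id for a in annotations]
        member = pd.Series(
            [g in set(gene_set.member_gene_ids) for g in membership_universe],
            index=pd.Index(membership_universe, name="gene_id"),
            dtype=int,
        )

        enrichment_frames = []
        for up, down in cfg.windows:
            tag = f"{up}up_{down}down"
            windows = [
                upstream_window(a, up, down, contig_length=contig_len[a.chrom])
                for a in annotations
            ]
            _write_tsv(
                windows_to_bed(windows),
                os.path.join(cfg.outdir, f"windows_{tag}.bed"),
                cfg,
                False,
            )
            seqs = {w.gene_id: extract_sequence(genome, w) for w in windows}
            stage = f"scan[{tag}]"
            counts_grid = count_motif_sites(seqs, library)
            _write_tsv(
                counts_grid, os.path.join(cfg.outdir, f"motif_counts_{tag}.tsv"), cfg, True
            )
            covs = pd.DataFrame(
                {
                    "gc": [gc_content(seqs[g])[0] for g in membership_universe],
                    "length": [len(seqs[g]) for g in membership_universe],
                },
                index=member.index,
            )
            stage = f"enrich[{tag}]"
            enr = run_motif_screen(
                counts_grid,
                member,
                covs,
                library,
                cfg.seed_gene_id,
                window_bp=up + down,
                min_sites=cfg.min_sites,
                predictor=cfg.predictor,
                basis_dim=cfg.basis_dim,
                alpha=cfg.gam_alpha,
            )
            _write_tsv(
                enr, os.path.join(cfg.outdir, f"enrichment_{tag}.tsv"), cfg, False
            )
            manifest["stages"][f"enrichment_{tag}"] = {
                "n_motifs_tested": len(enr),
                "n_fdr_05": int((enr["fdr"] < 0.05).sum()) if len(enr) else 0,
            }
            enrichment_frames.append((tag, enr, counts_grid))

        stage = "targets"
        from .targets import predict_targets

        tag, enr, counts_grid = enrichment_frames[-1]
        target_frames = []
        for motif_id in enr["motif_id"]:
            target_frames.append(
                predict_targets(counts_grid, corr, motif_id, top_n=cfg.top_n_targets)
            )
        if target_frames:
            _write_tsv(
                pd.concat(target_frames, ignore_index=True),
                os.path.join(cfg.outdir, f"targets_{tag}.tsv"),
                cfg,
                False,
            )
        manifest["stages"]["targets"] = {"n_motifs": len(target_frames)}
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "error"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["elapsed_s"] = round(time.time() - t0, 3)
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
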