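"""End-to-end pipeline orchestration from a declarative YAML config.

Stages run in methods order: filter -> structure -> rda -> outliers ->
scan -> project. Every default equals the study-standard parameter set
(MAF 0.05, het 0.50, sample call rate 0.80, |r| 0.70, VIF 5, 999 / 9,999
permutations, +/-3.29 SD, 20-kb windows, top 1%). All outputs are new
files under ``outdir``; a manifest records output paths, input SHA-256
hashes, and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envdata, genotype_io, landscape, popstructure, rda, selection_scan

logger = logging.getLogger(__name__)

STAGES = ["filter", "structure", "rda", "scan", "project"]


@dataclass
class PipelineConfig:
    vcf: str
    env: str
    outdir: str
    grids_current: str | None = None
    grids_future: list[str] = field(default_factory=list)
    gff: str | None = None
    maf: float = 0.05
    het: float = 0.50
    sample_callrate: float = 0.80
    prune_r: float = 0.70
    vif_max: float = 5.0
    keep_predictors: list[str] | None = None
    condition_pcs: int = 0  # 0 = no structure conditioning
    n_axes: int = 2
    sd_mult: float = 3.29
    rda_perms: int = 999
    mantel_perms: int = 9999
    window_bp: int = 20_000
    top_frac: float = 0.01
    kmax: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.vcf, self.env]
        if self.grids_current:
            paths.append(self.grids_current)
        paths += self.grids_future
        if self.gff:
            paths.append(self.gff)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, stage: str | None = None) -> dict:
    """Run all stages (or a single ``stage``) and return the manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [stage] if stage else STAGES
    manifest: dict = {
        "seed": cfg.seed,
        "inputs": {"vcf": _sha256(Path(cfg.vcf)), "env": _sha256(Path(cfg.env))},
        "outputs": {},
        "stages": {},
    }

    env = pd.read_csv(cfg.env)
    variables = envdata.variable_columns(env)

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    current = None
    for st in stages:
        t0 = time.time()
        try:
            if st == "filter":
                G = genotype_io.read_vcf(cfg.vcf)
                spec = genotype_io.VariantFilterSpec(cfg.maf, cfg.het, cfg.sample_callrate)
                G, report = genotype_io.filter_variants(G, spec)
                out = outdir / "filtered.vcf"
                genotype_io.write_vcf(G, out)
                record("filtered_vcf", out)
                rep = outdir / "filter_report.tsv"
                pd.Series(report).to_csv(rep, sep="\t", header=False)
                record("filter_report", rep)
            elif st == "structure":
                G = genotype_io.impute_modal(genotype_io.read_vcf(outdir / "filtered.vcf"))
                scores, pct = popstructure.genetic_pca(G)
                cm = popstructure.find_clusters(
                    scores, range(1, cfg.kmax + 1), seed=cfg.seed, retained_pcs=10
                )
                out = outdir / "clusters.tsv"
                pd.DataFrame(
                    {"sample": G.samples, "cluster": cm.assignments}
                ).to_csv(out, sep="\t", index=False)
                record("clusters", out)
            elif st == "rda":
                G = genotype_io.impute_modal(genotype_io.read_vcf(outdir / "filtered.vcf"))
                env_s = env.iloc[: G.n_samples].reset_index(drop=True)
                keep = cfg.keep_predictors
                if keep is None:
                    keep, _ = envdata.prune_correlated(env_s, cfg.prune_r, variables)
                means, sds = envdata.reference_stats(env_s, keep)
                X = envdata.standardize(env_s, means, sds)[keep].to_numpy()
                Y = G.calls.astype(float)
                Z = None
                if cfg.condition_pcs > 0:
                    pcs, _ = popstructure.genetic_pca(G)
                    Z = pcs[:, : cfg.condition_pcs]
                model = rda.fit_rda(Y, X, Z=Z, predictor_names=keep)
                outliers = rda.detect_outlier_loci(model, cfg.n_axes, cfg.sd_mult)
                outliers = rda.assign_env_driver(outliers, Y, X, keep)
                outliers = outliers.join(
                    G.loci[["chrom", "pos"]], on="locus_index"
                )
                out = outdir / "outliers.tsv"
                outliers.to_csv(out, sep="\t", index=False)
                record("outliers", out)
                _, p = rda.anova_permutation(Y, X, Z=Z, n_perm=cfg.rda_perms, seed=cfg.seed)
                summary = {
                    "n": model.n, "m": model.m, "predictors": keep,
                    "r2": model.r2, "adj_r2": model.adj_r2, "anova_p": p,
                    "eigenvalues": model.eigenvalues.tolist(),
                    "n_outliers": int(outliers["locus_index"].nunique()),
                }
                out = outdir / "rda_summary.json"
                out.write_text(json.dumps(summary, indent=2))
                record("rda_summary", out)
                current = (G, X, keep, model, outliers)
            elif st == "scan":
                G = genotype_io.impute_modal(genotype_io.read_vcf(outdir / "filtered.vcf"))
                env_s = env.iloc[: G.n_samples].reset_index(drop=True)
                var = variables[0]
                groups = selection_scan.quartile_groups(env_s, var)
                scan = selection_scan.windowed_weighted_fst(
                    G, groups, cfg.window_bp, cfg.window_bp, cfg.top_frac
                )
                out = outdir / f"fst_scan_{var}.tsv"
                scan.windows.to_csv(out, sep="\t", index=False)
                record(f"fst_scan_{var}", out)
            elif st == "project":
                if not cfg.grids_current or current is None:
                    logger.info("project stage skipped: no grids or fitted model")
                    continue
                G, X, keep, model, outliers = current
                Y = G.calls.astype(float)
                enr = landscape.enriched_rda(
                    Y, outliers["locus_index"].to_numpy(), X, predictor_names=keep
                )
                env_s = env.iloc[: G.n_samples].reset_index(drop=True)
                means, sds = envdata.reference_stats(env_s, keep)
                cur = envdata.standardize(envdata.read_grid_csv(cfg.grids_current), means, sds)
                ai_cur = landscape.adaptive_index(enr, cur, axes=list(range(1, cfg.n_axes + 1)))
                if cfg.grids_future:
                    fut_grids = [envdata.read_grid_csv(p) for p in cfg.grids_future]
                    fut = envdata.standardize(landscape.ensemble_mean(fut_grids), means, sds)
                    ai_fut = landscape.adaptive_index(
                        enr, fut, axes=list(range(1, cfg.n_axes + 1))
                    )
                    off = landscape.genomic_offset(ai_cur, ai_fut)
                    out = outdir / "genomic_offset.csv"
                    out_df = off.pixels.copy()
                    out_df["offset"] = off.offset
                    out_df.to_csv(out, index=False)
                    record("genomic_offset", out)
                out = outdir / "adaptive_index_current.csv"
                ai_df = ai_cur.pixels.copy()
                for k, ax in enumerate(ai_cur.axes):
                    ai_df[f"AI{ax}"] = ai_cur.values[:, k]
                ai_df.to_csv(out, index=False)
                record("adaptive_index_current", out)
        except Exception:
            logger.exception("stage %r failed", st)
            raise RuntimeError(f"pipeline stage {st!r} failed") from None
        manifest["stages"][st] = {"seconds": round(time.time() - t0, 3)}

    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return manifest
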