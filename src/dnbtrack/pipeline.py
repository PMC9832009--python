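"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages: simulate (optional) -> normalize -> trajectory -> dnb -> score ->
network (optional) -> report.  Every stage writes its outputs under the
configured directory; a JSON manifest records all parameters and seeds so
a rerun from the manifest reproduces deterministic stages byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dnb, io, signatures, trajectory
from .errors import ConfigError, DnbtrackError
from .simulate import SyntheticConfig, generate_timecourse

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("dnbtrack")


@dataclass
class PipelineConfig:
    """All inputs, stage toggles and stage parameters of one pipeline run."""

    out_dir: str = "dnbtrack_out"
    # inputs; when counts_path is None the synthetic generator is used
    counts_path: str | None = None
    design_path: str | None = None
    subspace_path: str | None = None  # one gene id per line
    adc_set_name: str | None = None  # names within gene_sets_path (GMT)
    scc_set_name: str | None = None
    gene_sets_path: str | None = None
    # stage parameters
    pseudocount: float = 1.0
    window: int = 1  # >1 switches the DNB stage to the sliding-window scan
    min_module_size: int = 5
    max_module_size: int = 200
    top_k_variable: int = 2000
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown pipeline config keys: {sorted(bad)}")
        return cls(synthetic=syn, **raw)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["time_points_weeks"] = list(d["synthetic"]["time_points_weeks"])
        d["synthetic"]["mean_log_expression"] = list(d["synthetic"]["mean_log_expression"])
        return d


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except DnbtrackError as exc:
                log.error("stage %s: FAILED: %s", name, exc)
                raise DnbtrackError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns a dict of key results and paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    fh = logging.FileHandler(out / "pipeline.log")
    log.addHandler(fh)
    results: dict = {}
    try:
        # --- acquire inputs -------------------------------------------------
        truth = None
        if cfg.counts_path is None:
            syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            counts, design, truth = _stage("simulate")(generate_timecourse)(syn)
            io.write_counts(counts, out / "counts.tsv")
            io.write_design(design, out / "design.csv")
            (out / "truth.json").write_text(
                json.dumps(
                    {
                        "module_gene_ids": truth.module_gene_ids,
                        "adc_marker_ids": truth.adc_marker_ids,
                        "scc_marker_ids": truth.scc_marker_ids,
                        "t_star_index": truth.t_star_index,
                        "t_star_weeks": truth.t_star_weeks,
                    },
                    indent=2,
                )
            )
        else:
            if cfg.design_path is None:
                raise ConfigError("design_path is required with counts_path")
            counts = _stage("read")(io.read_counts)(cfg.counts_path)
            design = io.read_design(cfg.design_path)
        design.validate_against(counts)

        # --- normalize ------------------------------------------------------
        expr = _stage("normalize")(io.normalize_rle)(counts, cfg.pseudocount)
        expr.to_frame().to_csv(out / "expression_log2rpm.tsv", sep="\t", index_label="gene_id")

        # --- trajectory -----------------------------------------------------
        emb = _stage("trajectory")(trajectory.pca_embed)(expr)
        emb.to_frame().to_csv(out / "pca_coordinates.tsv", sep="\t", index=False)
        disp = trajectory.timepoint_dispersion(emb, design)
        disp.to_csv(out / "dispersion.tsv", sep="\t", index=False)
        results["dispersion_peak_weeks"] = float(
            disp.loc[disp["is_max"], "time_weeks"].iloc[0]
        )

        # --- dnb ------------------------------------------------------------
        subspace = None
        if cfg.subspace_path:
            subspace = [
                line.strip()
                for line in Path(cfg.subspace_path).read_text().splitlines()
                if line.strip()
            ]
        scan = dnb.sliding_window_scan if cfg.window > 1 else dnb.dnb_scan
        kwargs = dict(
            subspace=subspace,
            min_size=cfg.min_module_size,
            max_size=cfg.max_module_size,
            top_k_variable=cfg.top_k_variable,
        )
        if cfg.window > 1:
            kwargs["window"] = cfg.window
        profile = _stage("dnb")(scan)(expr, design, **kwargs)
        profile.to_frame().to_csv(out / "ci_profile.tsv", sep="\t", index=False)
        _write_dominant_edges(profile, expr, design, out / "dominant_module_edges.tsv")
        (out / "ci_profile.json").write_text(
            json.dumps(
                {
                    "time_points": [float(t) for t in profile.time_points],
                    "ci": profile.ci,
                    "pcc_in": profile.pcc_in,
                    "pcc_out": profile.pcc_out,
                    "sd_in": profile.sd_in,
                    "tipping_point_index": profile.tipping_point_index,
                    "tipping_point_time": float(profile.tipping_point_time),
                    "dominant_modules": [list(m.members) for m in profile.dominant_modules],
                },
                indent=2,
            )
        )
        results["tipping_point_time"] = float(profile.tipping_point_time)
        results["tipping_point_index"] = profile.tipping_point_index
        if truth is not None:
            dom = set(profile.dominant_modules[profile.tipping_point_index].members)
            mod = set(truth.module_gene_ids)
            results["module_jaccard"] = len(dom & mod) / len(dom | mod)

        # --- score ----------------------------------------------------------
        adc_set = scc_set = None
        if cfg.gene_sets_path and cfg.adc_set_name and cfg.scc_set_name:
            sets = {s.name: s for s in io.read_gene_sets(cfg.gene_sets_path)}
            adc_set, scc_set = sets[cfg.adc_set_name], sets[cfg.scc_set_name]
        elif truth is not None:
            adc_set = io.GeneSet("ADC_up", truth.adc_marker_ids, "up")
            scc_set = io.GeneSet("SCC_up", truth.scc_marker_ids, "up")
        if adc_set and scc_set:
            ast = _stage("score")(signatures.ast_score)(expr, adc_set, scc_set)
            ast.to_frame().to_csv(out / "ast_scores.tsv", sep="\t", index=False)
            results["ast_range"] = [float(ast.ast.scores.min()), float(ast.ast.scores.max())]

        # --- manifest -------------------------------------------------------
        manifest = {"config": cfg.manifest(), "results": {k: v for k, v in results.items()}}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        results["out_dir"] = str(out)
        return results
    finally:
        log.removeHandler(fh)
        fh.close()


def _write_dominant_edges(profile, expr, design, path: Path) -> None:
    """Edge list (gene_a, gene_b, pcc) of the dominant module per time point."""
    import pandas as pd

    rows = []
    for ti, t in enumerate(profile.time_points):
        mod = profile.dominant_modules[ti]
        samples = design.samples_at(t) if t in design.time_points else None
        if not samples:  # sliding-window labels always map to real time points
            continue
        sub_genes = list(mod.members)
        idx = expr.gene_index(sub_genes)
        x = expr.subset_samples(samples).values[idx]
        if x.shape[1] < 3:
            continue
        r = np.corrcoef(x)
        for i in range(len(sub_genes)):
            for j in range(i + 1, len(sub_genes)):
                rows.append(
                    {
                        "time_weeks": t,
                        "gene_a": sub_genes[i],
                        "gene_b": sub_genes[j],
                        "pcc": r[i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
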