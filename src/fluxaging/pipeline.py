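"""End-to-end orchestration: counts -> normalization -> per-sample scoring
-> context extraction -> flux profiling -> group comparison -> summaries.

``run_pipeline`` executes the stages in order, producing one context model
and one flux column per sample, and writes TSV outputs plus a JSON
manifest (config echo, input hashes, warnings, per-stage timings). Output
tables are byte-deterministic for a fixed config and seed; only manifest
timings vary between reruns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .context_model import (
    DEFAULT_FORCED_PATHWAYS,
    DEFAULT_PERCENTILE_CUTS,
    extract_context_model,
    score_reactions,
)
from .expression import gene_zscores, normalize, preranked_gsea
from .flux_sim import atp_capacity, profile_fluxes
from .group_compare import compare_flux_table, pathway_summary, row_zscores
from .model_io import read_gmt, read_model, write_gmt, write_model, GeneSetCollection
from .synthetic_data import (
    CountMatrix,
    SyntheticDesign,
    make_toy_model,
    simulate_counts,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_demo"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for remediation."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults mirror the printed method constants."""

    model_path: str = ""
    counts_path: str = ""
    groups_path: str = ""
    gene_sets_path: str | None = None
    out_dir: str = "fluxaging_out"

    pseudocount: float = 1.0
    percentile_cuts: tuple = DEFAULT_PERCENTILE_CUTS
    forced_pathways: Sequence[str] = DEFAULT_FORCED_PATHWAYS
    no_gpr_policy: str = "median"

    penalty_low: float = 100.0
    penalty_mid: float = 1.0
    flux_threshold: float = 1e-6
    support_flux: float = 1.0
    maximize_only: bool = False

    vdw_method: str = "chi2"
    vdw_n_perm: int = 9999
    contrast: tuple = ("KO_old", "WT_old")
    contrast_group: str = "KO_old"

    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    gsea_min_size: int = 3

    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.percentile_cuts
        if not (0 < lo < hi < 100):
            raise PipelineError(
                "config", f"percentile cuts must be strictly increasing in (0,100), got {self.percentile_cuts}"
            )
        for label, path in (
            ("model_path", self.model_path),
            ("counts_path", self.counts_path),
            ("groups_path", self.groups_path),
        ):
            if not path or not Path(path).exists():
                raise PipelineError("config", f"{label} does not resolve: {path!r}")
        if self.gene_sets_path and not Path(self.gene_sets_path).exists():
            raise PipelineError("config", f"gene_sets_path does not resolve: {self.gene_sets_path!r}")
        if self.vdw_method not in ("chi2", "permutation"):
            raise PipelineError("config", f"vdw_method must be chi2|permutation, got {self.vdw_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.percentile_cuts, list):
            cfg.percentile_cuts = tuple(cfg.percentile_cuts)
        if isinstance(cfg.contrast, list):
            cfg.contrast = tuple(cfg.contrast)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percentile_cuts"] = list(self.percentile_cuts)
        d["forced_pathways"] = list(self.forced_pathways)
        d["contrast"] = list(self.contrast)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "failed"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "warnings": [],
        "timings_s": {},
        "outputs": [],
    }
    for key in ("model_path", "counts_path", "groups_path", "gene_sets_path"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    def emit(df: pd.DataFrame, name: str) -> None:
        _write_tsv(df, out / name)
        manifest["outputs"].append(name)

    stage = "load"
    try:
        t0 = time.perf_counter()
        model = read_model(config.model_path)
        counts = CountMatrix.from_tsv(config.counts_path, config.groups_path)
        gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "normalize"
        t0 = time.perf_counter()
        expr = normalize(counts, pseudocount=config.pseudocount)
        emit(expr.values, "expression.tsv")
        emit(expr.size_factors.rename("size_factor").to_frame(), "size_factors.tsv")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "context_models"
        t0 = time.perf_counter()
        (out / "confidence").mkdir(exist_ok=True)
        flux_cols: dict = {}
        status_cols: dict = {}
        atpm_caps: dict = {}
        all_rxns = model.reaction_ids
        imputed_reported = False
        for sample in expr.samples:
            conf = score_reactions(
                model,
                expr.values[sample],
                forced_pathways=config.forced_pathways,
                percentile_cuts=config.percentile_cuts,
                no_gpr_policy=config.no_gpr_policy,
            )
            if conf.imputed_genes and not imputed_reported:
                manifest["warnings"].append(
                    f"genes imputed with matrix minimum (absent from counts): {conf.imputed_genes}"
                )
                imputed_reported = True
            _write_tsv(conf.table, out / "confidence" / f"{sample}.tsv")
            ctx = extract_context_model(
                model,
                conf,
                penalty_low=config.penalty_low,
                penalty_mid=config.penalty_mid,
                flux_threshold=config.flux_threshold,
                support_flux=config.support_flux,
            )
            if ctx.blocked:
                manifest["warnings"].append(
                    f"sample {sample}: score-3 reaction(s) cannot carry flux: {ctx.blocked}"
                )
            fluxes, status = profile_fluxes(
                ctx.model,
                flux_threshold=config.flux_threshold,
                maximize_only=config.maximize_only,
            )
            flux_cols[sample] = pd.Series(
                [fluxes.get(r, 0.0) for r in all_rxns], index=all_rxns
            )
            status_cols[sample] = pd.Series(
                [status.get(r, "excluded") for r in all_rxns], index=all_rxns
            )
            if ctx.model.atpm_id is not None:
                atpm_caps[sample] = atp_capacity(ctx.model)
            elif model.atpm_id is not None:
                atpm_caps[sample] = 0.0
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)
        manifest["n_context_models"] = len(expr.samples)

        stage = "flux_table"
        flux_table = pd.DataFrame(flux_cols)
        flux_table.index.name = "reaction"
        # drop reactions excluded from every sample's context model
        status_table = pd.DataFrame(status_cols)
        status_table.index.name = "reaction"
        in_any = (status_table != "excluded").any(axis=1)
        flux_table = flux_table.loc[in_any]
        status_table = status_table.loc[in_any]
        emit(flux_table, "flux_table.tsv")
        emit(status_table, "flux_status.tsv")
        if atpm_caps:
            emit(
                pd.Series(atpm_caps, name="atp_capacity").rename_axis("sample").to_frame(),
                "atp_capacity.tsv",
            )

        stage = "group_compare"
        t0 = time.perf_counter()
        subsystems = {r.id: r.subsystem for r in model.reactions}
        result = compare_flux_table(
            flux_table,
            counts.groups,
            method=config.vdw_method,
            n_perm=config.vdw_n_perm,
            seed=config.seed,
            subsystems=subsystems,
        )
        emit(result, "comparison.tsv")
        n_degen = int(result["degenerate"].sum())
        if n_degen:
            manifest["warnings"].append(
                f"{n_degen} reaction row(s) degenerate (constant flux); excluded from heatmaps"
            )
        zdf, zero_flags = row_zscores(flux_table)
        emit(zdf.loc[~zero_flags], "row_zscores.tsv")
        summary = pathway_summary(
            result, zdf, subsystems, counts.groups, contrast_group=config.contrast_group
        )
        emit(summary, "pathway_summary.tsv")
        # within-group flux SD diagnostic (reported, not optimized over)
        sd_cols = {
            g: flux_table[[s for s in flux_table.columns if counts.groups[s] == g]].std(
                axis=1, ddof=1
            )
            for g in dict.fromkeys(counts.groups.values())
        }
        emit(pd.DataFrame(sd_cols), "flux_sd_within_group.tsv")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "expression_stats"
        t0 = time.perf_counter()
        zt = gene_zscores(expr, config.contrast)
        emit(zt, "gene_zscores.tsv")
        if gene_sets is not None:
            gsea = preranked_gsea(
                zt["z"],
                gene_sets,
                weight=config.gsea_weight,
                n_perm=config.gsea_n_perm,
                min_size=config.gsea_min_size,
                seed=config.seed,
            )
            emit(gsea, "gsea.tsv")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)
    except PipelineError:
        failed_marker.write_text(f"stage: {stage}\n")
        raise
    except Exception as e:  # annotate any stage failure with its stage name
        failed_marker.write_text(f"stage: {stage}\n{e}\n")
        raise PipelineError(stage, str(e)) from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def make_demo(
    out_dir,
    seed: int = 1,
    replicates: int | None = None,
    n_linear_pathways: int = 12,
    suppression_lfc: float = -2.0,
) -> Path:
    """Materialize a ready-to-run synthetic workspace; returns the config path.

    Writes the toy model (JSON), counts + groups TSVs, a subsystem-derived
    GMT, and a config.yaml. The demo config leaves ``forced_pathways``
    empty: on a self-contained toy network, forcing a pathway guarantees
    its full flux regardless of expression, which would mask the planted
    signal by construction (see docs/methods.md).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = SyntheticDesign(seed=seed, suppression_lfc=suppression_lfc)
    if replicates is not None:
        design = SyntheticDesign(
            seed=seed, suppression_lfc=suppression_lfc, replicates=replicates
        )
    model = make_toy_model(n_linear_pathways=n_linear_pathways, seed=seed)
    counts = simulate_counts(model, design)

    write_model(model, out / "model.json")
    counts.to_tsv(out / "counts.tsv", out / "groups.tsv")
    sets: dict = {}
    for r in model.reactions:
        if r.gpr.is_empty:
            continue
        sets.setdefault(r.subsystem, [])
        for g in sorted(r.gpr.genes):
            if g not in sets[r.subsystem]:
                sets[r.subsystem].append(g)
    write_gmt(GeneSetCollection(sets), out / "gene_sets.gmt")

    config = PipelineConfig(
        model_path=str(out / "model.json"),
        counts_path=str(out / "counts.tsv"),
        groups_path=str(out / "groups.tsv"),
        gene_sets_path=str(out / "gene_sets.gmt"),
        out_dir=str(out / "results"),
        forced_pathways=[],
        seed=seed,
    )
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return cfg_path
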