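"""End-to-end drivers: simulation -> clocks -> meta-EWAS -> enrichment.

A run is described by a :class:`RunConfig` (YAML/JSON-friendly dict) with a
mandatory global seed. Every stage draws its randomness from a named
substream derived from that seed, so enabling or disabling one stage does
not perturb the others, and a repeated run writes byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .clock import CVResult, loocv, losocv
from .enrichment import region_set_enrichment, rows_to_frame
from .ewas import bonferroni_threshold, run_strata, select_top, two_step_meta
from .simulate import SimulationScenario, generate_annotation_fixture, generate_panel
from .transform import TransformSpec
from .types import ValidationError

logger = logging.getLogger(__name__)

DEFAULTS = {
    "min_stratum_n": 15,  # smallest stratum entering the EWAS
    "top_n": 1000,        # CpGs per direction carried into enrichment
    "tf_buffer_bp": 200,  # buffer around CpGs for TF overlap
    "alpha": 0.5,         # elastic-net mixing parameter
    "bonferroni_alpha": 0.05,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``scenario`` (simulation parameters) or ``inputs``
    (paths to panel/beta/CpG-map files) must be given.
    """

    seed: int
    out_dir: str
    scenario: dict | None = None
    inputs: dict | None = None
    clocks: tuple[str, ...] = ("all", "blood", "skin")
    ewas_analyses: tuple[str, ...] = ("age-all", "age-blood", "age-skin", "sex")
    run_enrichment: bool = True
    enrichment_factor: float = 5.0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise ValidationError("exactly one of scenario/inputs must be provided")
        if self.seed is None:
            raise ValidationError("a global seed is mandatory")
        self.thresholds = {**DEFAULTS, **self.thresholds}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("clocks", "ewas_analyses"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def derive_seed(master: int, name: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return (int(master) * 1000003 + zlib.crc32(name.encode())) % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    manifest: dict = {
        "seed": config.seed,
        "thresholds": th,
        "stage_seeds": {},
        "inputs": {},
        "outputs": [],
        "summaries": {},
    }

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    stage = "simulate" if config.scenario is not None else "load"
    try:
        if config.scenario is not None:
            sim_seed = derive_seed(config.seed, "simulation")
            manifest["stage_seeds"]["simulation"] = sim_seed
            scenario = SimulationScenario(**{**config.scenario, "seed": sim_seed})
            panel, betas, cpg_map, truth = generate_panel(scenario)
            cio.write_sample_panel(panel, out / "panel.csv")
            cio.write_cpg_map(cpg_map, out / "cpg_map.csv")
            record(out / "panel.csv")
            record(out / "cpg_map.csv")
        else:
            paths = {k: Path(v) for k, v in config.inputs.items()}
            panel = cio.read_sample_panel(paths["panel"])
            betas = cio.read_beta_matrix(paths["betas"], panel)
            cpg_map = cio.read_cpg_map(paths["cpg_map"]) if "cpg_map" in paths else None
            truth = None
            manifest["inputs"] = {k: _digest(p) for k, p in paths.items()}

        stage = "clocks"
        cv_seed = derive_seed(config.seed, "cv-folds")
        manifest["stage_seeds"]["cv-folds"] = cv_seed
        spec = TransformSpec()
        for tissue in config.clocks:
            mask = (
                np.ones(len(panel), dtype=bool)
                if tissue == "all"
                else np.asarray([t == tissue for t in panel.tissue])
            )
            if not mask.any():
                logger.warning("clock %s skipped: no samples", tissue)
                continue
            sub_p, sub_b = panel.subset(mask), betas.subset_samples(mask)
            loo = loocv(sub_b, sub_p, spec, alpha=th["alpha"], seed=cv_seed)
            _write_tsv(loo.predictions, out / f"clock_{tissue}_loo.tsv")
            record(out / f"clock_{tissue}_loo.tsv")
            summary: dict = {"loo": loo.summary}
            if len(set(sub_p.species)) >= 3:
                loso = losocv(sub_b, sub_p, spec, alpha=th["alpha"], seed=cv_seed)
                _write_tsv(loso.predictions, out / f"clock_{tissue}_loso.tsv")
                record(out / f"clock_{tissue}_loso.tsv")
                summary["loso"] = loso.summary
            manifest["summaries"][f"clock_{tissue}"] = summary

        stage = "ewas"
        metas = {}
        age_strata = run_strata(betas, panel, kind="age", min_n=th["min_stratum_n"])
        sex_strata = run_strata(betas, panel, kind="sex", min_n=th["min_stratum_n"])
        n_tested = len(betas.cpg_ids)
        bonf = bonferroni_threshold(n_tested, th["bonferroni_alpha"])
        for analysis in config.ewas_analyses:
            strata = sex_strata if analysis == "sex" else age_strata
            try:
                meta = two_step_meta(strata, analysis)
            except ValidationError as exc:
                logger.warning("EWAS %s skipped: %s", analysis, exc)
                continue
            metas[analysis] = meta
            _write_tsv(meta.table, out / f"ewas_{analysis}.tsv")
            record(out / f"ewas_{analysis}.tsv")
            n_sig = int((meta.table["log_p"] < np.log(bonf)).sum())
            manifest["summaries"][f"ewas_{analysis}"] = {
                "n_strata": meta.n_strata,
                "n_cpgs": len(meta.table),
                "bonferroni_threshold": bonf,
                "n_significant": n_sig,
            }

        if config.run_enrichment and "age-all" in metas and cpg_map is not None:
            stage = "enrichment"
            if truth is None:
                logger.warning("enrichment stage requires simulated annotations; skipped")
            else:
                ann_seed = derive_seed(config.seed, "annotations")
                manifest["stage_seeds"]["annotations"] = ann_seed
                region_sets = generate_annotation_fixture(
                    truth, cpg_map, config.enrichment_factor, seed=ann_seed
                )
                states = [rs for rs in region_sets if rs.source_label is None][:4]
                background = list(betas.cpg_ids)
                fg = select_top(metas["age-all"], n=th["top_n"], direction="positive")
                rows = region_set_enrichment(fg, background, states, cpg_map)
                frame = rows_to_frame(rows).sort_values(
                    "log10_p_enrichment", kind="mergesort"
                )
                _write_tsv(frame, out / "enrichment_states_positive.tsv")
                record(out / "enrichment_states_positive.tsv")
                top = frame.iloc[0]
                manifest["summaries"]["enrichment"] = {
                    "top_set": str(top["set_name"]),
                    "top_fold_change": float(top["fold_change"]),
                    "top_log10_p": float(top["log10_p_enrichment"]),
                }
    except ValidationError as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise ValidationError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def summarize_run(manifest: dict) -> str:
    """Human-readable report of a completed (or partial) run."""
    lines = [f"cetclock run (seed={manifest.get('seed')})"]
    if "failed_stage" in manifest:
        lines.append(f"  INCOMPLETE: failed at stage {manifest['failed_stage']}")
    summ = manifest.get("summaries", {})
    clock_keys = [k for k in summ if k.startswith("clock_")]
    if clock_keys:
        lines.append("clocks (N, Pearson r, median MAE years):")
        for k in clock_keys:
            s = summ[k]["loo"]
            lines.append(
                f"  {k.removeprefix('clock_'):>6} LOO: N={s['n']} "
                f"r={s['pearson_r']:.3f} MAE={s['median_mae_years']:.2f}"
            )
            if "loso" in summ[k]:
                s = summ[k]["loso"]
                lines.append(
                    f"  {'':>6} LOSO: rm-r={s['repeated_measures_r']:.3f} "
                    f"MAE={s['median_mae_years']:.2f}"
                )
    else:
        lines.append("clocks: skipped")
    ewas_keys = [k for k in summ if k.startswith("ewas_")]
    if ewas_keys:
        lines.append("EWAS (CpGs beyond the Bonferroni line):")
        for k in ewas_keys:
            s = summ[k]
            lines.append(
                f"  {k.removeprefix('ewas_'):>9}: {s['n_significant']}/{s['n_cpgs']} "
                f"(threshold {s['bonferroni_threshold']:.2e}, {s['n_strata']} strata)"
            )
    else:
        lines.append("EWAS: skipped")
    if "enrichment" in summ:
        s = summ["enrichment"]
        lines.append(
            f"top enrichment: {s['top_set']} FC={s['top_fold_change']:.2f} "
            f"log10 p={s['top_log10_p']:.1f}"
        )
    else:
        lines.append("enrichment: skipped")
    return "\n".join(lines)
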