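"""End-to-end orchestration: simulate -> prioritize -> burden -> CNV ->
validation report, as one reproducible seeded run.

Every stage is a pure function of (inputs, config, seed): the run writes
all simulated inputs to ``<outdir>/inputs``, reads them back through the
package readers (so the on-disk round trip is part of the pipeline), and
writes the report bundle plus a resolved-config snapshot to
``<outdir>/report``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io
from .cnv_recurrence import (
    calls_from_frame,
    classify_rare_cnv,
    cluster_and_merge,
    presence_matrix,
    qc_filter_calls,
    recurrence_candidates,
    scan_depth_for_deletion,
)
from .config import SimulationConfig
from .gene_burden import GenotypeMatrix, run_burden_scan
from .synthetic_cohort import (
    simulate_cnv_calls,
    simulate_cohort_variants,
    simulate_depth_profile,
    simulate_frequency_track,
    simulate_phenotypes,
    simulate_qpcr,
)
from .validation_reporting import (
    cn_group_regression,
    ddct_relative_cn,
    qpcr_samples_from_frame,
    summarize_cohort,
    variant_spectrum,
    write_report,
)
from .variant_prioritization import FilterThresholds, prioritize_variants

logger = logging.getLogger("q22screen")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_all"]

_STAGES = ("simulate", "prioritize", "burden", "cnv", "report")


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every offending field."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid config: " + "; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    """Resolved pipeline configuration with study-default thresholds.

    Defaults: SNP/indel hard filters as in :class:`FilterThresholds`,
    rarity cutoff 1%, 10,000 permutations, CNV QC at p < 0.01 / size >
    1 kb / q0 <= 0.5, recurrence threshold 0.5 (>60% is the stricter
    published reading; both are discussed in the methods note), DGV rarity
    at <=50% overlap with >1%-frequency regions, and the deletion scan at
    0.7x with a 51-bin rolling median and 500 kb minimum span.
    """

    outdir: str = "q22screen_run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    maf_cutoff: float = 0.01
    n_perm: int = 10_000
    recurrence_threshold: float = 0.5
    cnv_p_max: float = 0.01
    cnv_min_size: int = 1_000
    cnv_q0_max: float = 0.5
    dgv_freq_cutoff: float = 0.01
    dgv_overlap_cutoff: float = 0.5
    deletion_ratio_cutoff: float = 0.7
    deletion_min_length: int = 500_000
    deletion_smooth_window: int = 51
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def validate_config(raw: Mapping) -> RunConfig:
    """Normalize a raw mapping into a :class:`RunConfig`.

    Unknown keys are rejected; out-of-range values are reported together,
    each naming its field.
    """
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    raw = dict(raw)
    unknown = sorted(set(raw) - known)
    for k in unknown:
        errors.append(f"unknown key {k!r}")
        raw.pop(k)
    if "sim" in raw and raw["sim"] is not None and not isinstance(raw["sim"], SimulationConfig):
        try:
            raw["sim"] = SimulationConfig.from_dict(raw["sim"])
        except (TypeError, ValueError) as exc:
            errors.append(f"sim: {exc}")
            raw.pop("sim")
    if "stages" in raw:
        stages = tuple(raw["stages"])
        bad = [s for s in stages if s not in _STAGES]
        if bad:
            errors.append(f"stages: unknown stage(s) {bad}")
        raw["stages"] = stages
    cfg = RunConfig(**raw)
    if not 0 < cfg.maf_cutoff <= 1:
        errors.append(f"maf_cutoff must be in (0, 1] (got {cfg.maf_cutoff})")
    if cfg.n_perm < 1:
        errors.append(f"n_perm must be >= 1 (got {cfg.n_perm})")
    for name in ("recurrence_threshold", "cnv_p_max", "cnv_q0_max",
                 "dgv_freq_cutoff", "dgv_overlap_cutoff"):
        v = getattr(cfg, name)
        if not 0 <= v <= 1:
            errors.append(f"{name} must be in [0, 1] (got {v})")
    if cfg.deletion_ratio_cutoff <= 0 or cfg.deletion_ratio_cutoff >= 1:
        errors.append("deletion_ratio_cutoff must be in (0, 1)")
    for name in ("cnv_min_size", "deletion_min_length", "deletion_smooth_window"):
        if getattr(cfg, name) < 1:
            errors.append(f"{name} must be >= 1")
    if errors:
        raise ConfigError(errors)
    return cfg


def _stage(config: RunConfig, name: str) -> bool:
    return name in config.stages


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns a summary dict with the
    key outputs and written paths. Identical config + seed gives identical
    outputs."""
    outdir = Path(config.outdir)
    inputs = outdir / "inputs"
    report_dir = outdir / "report"
    inputs.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    logger.info("run_all seed=%s outdir=%s stages=%s", config.seed, outdir, config.stages)

    summary: dict = {"outdir": str(outdir), "seed": config.seed}

    # ---- simulate ----------------------------------------------------
    if not _stage(config, "simulate"):
        raise ConfigError(["the simulate stage is required for a self-contained run"])
    try:
        records, annotations, manifest = simulate_cohort_variants(sim)
        samples = (
            manifest["samples"]["cases"]
            + manifest["samples"]["controls"]
            + (list(manifest["samples"]["trio"].values()) if manifest["samples"]["trio"] else [])
        )
        io.write_vcf(records, samples, inputs / "cohort.vcf",
                     chrom=sim.chrom, chrom_length=sim.region_length)
        io.write_annotations(annotations, inputs / "annotations.tsv")
        io.write_manifest(manifest, inputs / "manifest.json")
        cnv_df = simulate_cnv_calls(sim)
        io.write_table(cnv_df, inputs / "cnv_calls.tsv")
        io.write_frequency_track(simulate_frequency_track(sim), inputs / "population_cnv.bed")
        child_profile = simulate_depth_profile(sim, "child")
        io.write_depth_profile(child_profile, inputs / "depth_child.tsv")
        io.write_table(simulate_phenotypes(sim), inputs / "phenotypes.tsv")
        io.write_table(simulate_qpcr(sim), inputs / "qpcr.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # ---- read back through the package readers ----------------------
    records, _ = io.read_vcf(inputs / "cohort.vcf")
    annotations = io.read_annotations(inputs / "annotations.tsv")
    manifest = io.read_manifest(inputs / "manifest.json")
    roles = manifest["samples"]
    trio = roles["trio"]
    trio_tuple = (trio["child"], trio["father"], trio["mother"]) if trio else None

    # ---- prioritize --------------------------------------------------
    prioritized, funnel = [], {}
    if _stage(config, "prioritize"):
        try:
            prioritized, funnel = prioritize_variants(
                records,
                annotations,
                thresholds=FilterThresholds(),
                maf_cutoff=config.maf_cutoff,
                trio=trio_tuple,
            )
            io.write_prioritized(prioritized, outdir / "prioritized.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage 'prioritize' failed: {exc}") from exc
        summary["funnel"] = funnel

    # ---- burden ------------------------------------------------------
    burden_table = pd.DataFrame()
    if _stage(config, "burden"):
        try:
            qualifying = {v.key: v.gene for v in prioritized}
            matrix = GenotypeMatrix.from_records(
                records, roles["cases"], roles["controls"], qualifying
            )
            burden_table = run_burden_scan(
                matrix, n_perm=config.n_perm, seed=config.seed
            )
            io.write_table(burden_table, outdir / "burden.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage 'burden' failed: {exc}") from exc
        summary["top_gene"] = (
            str(burden_table.iloc[0]["gene"]) if len(burden_table) else None
        )

    # ---- cnv ---------------------------------------------------------
    candidates_df = pd.DataFrame()
    deletion_df = pd.DataFrame()
    if _stage(config, "cnv"):
        try:
            cnv_df = io.read_table(inputs / "cnv_calls.tsv")
            track = io.read_frequency_track(inputs / "population_cnv.bed")
            case_calls = calls_from_frame(cnv_df[cnv_df["role"] == "case"])
            parent_calls = calls_from_frame(
                cnv_df[cnv_df["role"].isin(["father", "mother"])]
            )
            kept = qc_filter_calls(
                case_calls,
                p_max=config.cnv_p_max,
                min_size=config.cnv_min_size,
                q0_max=config.cnv_q0_max,
            )
            parent_kept = qc_filter_calls(
                parent_calls,
                p_max=config.cnv_p_max,
                min_size=config.cnv_min_size,
                q0_max=config.cnv_q0_max,
            )
            merged = cluster_and_merge(kept)
            candidates = recurrence_candidates(
                merged,
                n_cases=len(roles["cases"]),
                parent_calls=parent_kept,
                threshold=config.recurrence_threshold,
            )
            rows = []
            for m in candidates:
                rows.append(
                    dict(
                        chrom=m.chrom,
                        start=m.start,
                        end=m.end,
                        cnv_type=m.cnv_type,
                        n_supporting=len(m.supporting_samples),
                        recurrence_rate=m.recurrence_rate,
                        present_in_parents=m.present_in_parents,
                        rare=classify_rare_cnv(
                            m,
                            track,
                            freq_cutoff=config.dgv_freq_cutoff,
                            overlap_cutoff=config.dgv_overlap_cutoff,
                        ),
                    )
                )
            candidates_df = pd.DataFrame(
                rows,
                columns=[
                    "chrom", "start", "end", "cnv_type", "n_supporting",
                    "recurrence_rate", "present_in_parents", "rare",
                ],
            )
            io.write_table(candidates_df, outdir / "cnv_candidates.tsv")
            io.write_table(
                presence_matrix(candidates, roles["cases"]).reset_index(names="candidate"),
                outdir / "cnv_presence.tsv",
            )
            child = io.read_depth_profile(inputs / "depth_child.tsv")
            dels = scan_depth_for_deletion(
                child,
                ratio_cutoff=config.deletion_ratio_cutoff,
                min_length=config.deletion_min_length,
                smooth_window=config.deletion_smooth_window,
            )
            deletion_df = pd.DataFrame(
                [
                    dict(sample_id=d.sample_id, start=d.start, end=d.end,
                         mean_normalized_depth=d.mean_normalized_depth)
                    for d in dels
                ],
                columns=["sample_id", "start", "end", "mean_normalized_depth"],
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'cnv' failed: {exc}") from exc
        summary["n_cnv_candidates"] = len(candidates_df)
        summary["deletions"] = deletion_df.to_dict("records")

    # ---- report ------------------------------------------------------
    if _stage(config, "report"):
        try:
            phenotypes = io.read_table(inputs / "phenotypes.tsv")
            qpcr_df = io.read_table(inputs / "qpcr.tsv")
            batch = qpcr_samples_from_frame(qpcr_df)
            rel = ddct_relative_cn(batch)
            by_id = {r.sample_id: r.rel_cn for r in rel}
            reg = cn_group_regression(
                [by_id[s.sample_id] for s in batch],
                [s.group for s in batch],
                [s.age for s in batch],
                [s.sex for s in batch],
            )
            cohort = summarize_cohort(phenotypes, sporadic_only=True)
            spectrum = variant_spectrum(records, annotations, roles["cases"])
            write_report(
                report_dir,
                funnel=funnel,
                burden_table=burden_table,
                cnv_candidates=candidates_df,
                deletion_calls=deletion_df,
                cohort_summary=cohort,
                qpcr_summary=reg,
                spectrum=spectrum,
            )
            (report_dir / "resolved_config.json").write_text(
                json.dumps(config.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'report' failed: {exc}") from exc
        summary["qpcr_group_p"] = reg["group_p"]
        summary["report_dir"] = str(report_dir)
    return summary
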