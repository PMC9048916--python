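"""End-to-end orchestration: one reproducible run from config to report.

A run either simulates a study (with ground truth retained alongside the
outputs) or reads GPR-dialect scans from disk, then executes the fixed
stage order: normalization cascade -> fold changes & cold-response calls ->
local occupancy analysis -> splicing efficiency -> summary report.  Every
threshold and the seed are echoed into a machine-readable manifest; manifest
plus seed reproduce the run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .normalize import DEFAULT_FLOOR, DEFAULT_SATURATION, normalize_scans
from .pausing import call_redistributed_probes, density_summaries, occupancy_ratios, relative_occupancy
from .plastome import (
    PlastomeAnnotation,
    StudyDesign,
    assign_probes,
    default_annotation,
    default_probe_layout,
    read_annotation,
    read_probe_layout,
)
from .simulate import ArrayScan, NoiseModel, TruthTable, cold_shift_preset, read_gpr, simulate_study, write_gpr
from .stats import (
    calls_frame,
    classify_cold_responsive,
    fold_changes,
    percentile_thresholds,
    splicing_efficiency,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    simulate: bool = True
    effects: str = "cold_preset"  # or "null"
    seed: int = 1
    annotation_path: str | None = None
    probes_path: str | None = None
    scans_dir: str | None = None
    out_dir: str = "results/run"
    # QC / normalization
    floor: float = DEFAULT_FLOOR
    saturation_level: float = DEFAULT_SATURATION
    min_probes: int = 2
    dye_swap: bool = False
    # classification
    fc_threshold: float = 1.5
    q_max: float = 0.1
    min_total: int = 3
    min_consec: int = 2
    top_frac: float = 0.10
    pi0_method: str = "fixed_1"
    # pausing / splicing
    pausing_fold: float = 2.0
    min_exon_len: int = 10
    # generator
    write_scans: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    design: StudyDesign
    annotation: PlastomeAnnotation
    abundances: pd.DataFrame
    fold_change_table: pd.DataFrame
    calls: list
    occupancy_ratio_table: pd.DataFrame
    density_table: pd.DataFrame
    redistribution_calls: list
    redistribution_rollup: pd.DataFrame
    splicing_table: pd.DataFrame
    splicing_excluded: list
    summary: dict
    manifest: dict
    truth: TruthTable | None = None


def _load_inputs(config: RunConfig):
    if config.annotation_path:
        annotation = read_annotation(config.annotation_path)
    else:
        annotation = default_annotation()
    if config.probes_path:
        layout = read_probe_layout(config.probes_path)
    else:
        layout = default_probe_layout(annotation)
    probes = assign_probes(layout, annotation)
    return annotation, probes


def _load_scans(config: RunConfig, design: StudyDesign) -> list[ArrayScan]:
    scans = []
    base = Path(config.scans_dir)
    for layer in design.layers:
        for tp in [design.baseline_label] + design.timepoint_labels:
            for rep in design.replicates:
                path = base / f"{layer}_{tp}_r{rep}.gpr"
                if not path.exists():
                    raise FileNotFoundError(f"missing scan {path}")
                scans.append(read_gpr(path, layer, tp, rep))
    return scans


def run_pipeline(config: RunConfig, design: StudyDesign | None = None,
                 noise: NoiseModel | None = None) -> PipelineResult:
    """Execute the full analysis and write all outputs under out_dir."""
    design = design or StudyDesign()
    annotation, probes = _load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulate:
        effects = [] if config.effects == "null" else cold_shift_preset(probes)
        scans, truth = simulate_study(design, annotation, probes, effects, noise or NoiseModel(), config.seed)
        if config.write_scans:
            scans_dir = out / "scans"
            scans_dir.mkdir(exist_ok=True)
            for scan in scans:
                write_gpr(scan, scans_dir / f"{scan.layer}_{scan.timepoint}_r{scan.replicate}.gpr")
    elif config.scans_dir:
        scans = _load_scans(config, design)
    else:
        raise ValueError("config must set simulate: true or a scans_dir")

    logger.info("normalizing %d scans", len(scans))
    abundances, exon_abundances, signal_table, norm_manifest = normalize_scans(
        scans, probes, floor=config.floor, saturation_level=config.saturation_level,
        min_probes=config.min_probes, dye_swap=config.dye_swap,
    )

    logger.info("computing fold changes")
    fc = fold_changes(abundances, design, pi0_method=config.pi0_method)
    calls = classify_cold_responsive(
        fc, design, threshold=config.fc_threshold, q_max=config.q_max,
        min_total=config.min_total, min_consec=config.min_consec,
    )
    cuts = percentile_thresholds(fc["log2fc_output"].dropna(), top_frac=config.top_frac)

    logger.info("local occupancy analysis")
    occ = relative_occupancy(signal_table)
    ratios = occupancy_ratios(occ, design, pi0_method=config.pi0_method)
    density = density_summaries(ratios)
    red_calls, rollup = call_redistributed_probes(
        ratios, design, fold=config.pausing_fold, q_max=config.q_max,
        min_consec=config.min_consec,
    )

    logger.info("splicing efficiency")
    splicing, spl_excluded = splicing_efficiency(
        exon_abundances, annotation, design,
        min_exon_len=config.min_exon_len, pi0_method=config.pi0_method,
    )

    summary = summarize_calls(calls, annotation)
    summary["percentile_low_cut"] = cuts.low_cut
    summary["percentile_high_cut"] = cuts.high_cut
    summary["n_redistributed_genes_up"] = int((rollup["direction"] == "up").sum()) if len(rollup) else 0
    summary["n_redistributed_genes_down"] = int((rollup["direction"] == "down").sum()) if len(rollup) else 0

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "normalization": norm_manifest.as_dict(),
        "stage_rows": {
            "abundances": len(abundances),
            "fold_changes": len(fc),
            "response_calls": len(calls),
            "occupancy_ratios": len(ratios),
            "redistribution_calls": len(red_calls),
            "splicing": len(splicing),
        },
    }

    _write_outputs(out, abundances, fc, calls, ratios, density, red_calls, rollup,
                   splicing, spl_excluded, summary, manifest, truth)

    return PipelineResult(
        config=config, design=design, annotation=annotation, abundances=abundances,
        fold_change_table=fc, calls=calls, occupancy_ratio_table=ratios,
        density_table=density, redistribution_calls=red_calls,
        redistribution_rollup=rollup, splicing_table=splicing,
        splicing_excluded=spl_excluded, summary=summary, manifest=manifest, truth=truth,
    )


def _write_outputs(out: Path, abundances, fc, calls, ratios, density, red_calls,
                   rollup, splicing, spl_excluded, summary, manifest, truth) -> None:
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    abundances.to_csv(out / "orf_abundances.tsv", **fmt)
    fc.to_csv(out / "fold_changes.tsv", **fmt)
    calls_frame(calls).to_csv(out / "response_calls.tsv", **fmt)
    ratios.to_csv(out / "occupancy_ratios.tsv", **fmt)
    density.to_csv(out / "density_summaries.tsv", **fmt)
    pd.DataFrame(
        {
            "probe_id": [c.probe_id for c in red_calls],
            "gene": [c.gene for c in red_calls],
            "direction": [c.direction for c in red_calls],
            "timepoints": [",".join(c.timepoints) for c in red_calls],
        }
    ).to_csv(out / "redistribution_calls.tsv", **fmt)
    rollup.to_csv(out / "redistribution_genes.tsv", **fmt)
    splicing.to_csv(out / "splicing_efficiency.tsv", **fmt)
    pd.DataFrame(spl_excluded, columns=["gene", "reason"]).to_csv(out / "splicing_excluded.tsv", **fmt)
    if truth is not None:
        truth.effects.to_csv(out / "truth_effects.tsv", **fmt)
        truth.responsive.to_csv(out / "truth_responsive.tsv", **fmt)
        truth.pausing.to_csv(out / "truth_pausing.tsv", **fmt)
        truth.splicing.to_csv(out / "truth_splicing.tsv", **fmt)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def summarize_calls(calls: list, annotation: PlastomeAnnotation) -> dict:
    """Essentiality breakdown of the cold-responsive calls.

    Counts and fractions of essential/nonessential genes genome-wide, among
    responsive genes (split by direction) and among the rest.
    """
    for c in calls:
        if c.gene not in annotation:
            raise KeyError(f"called gene {c.gene!r} absent from annotation")
    all_genes = annotation.gene_names
    resp_genes = [c.gene for c in calls]
    non_resp = [g for g in all_genes if g not in set(resp_genes)]

    def split(genes):
        ess, noness = annotation.essential_split(genes)
        n = len(genes)
        return {
            "n": n,
            "essential": ess,
            "nonessential": noness,
            "frac_essential": ess / n if n else 0.0,
            "frac_nonessential": noness / n if n else 0.0,
        }

    return {
        "n_responsive": len(resp_genes),
        "n_up": sum(1 for c in calls if c.direction == "up"),
        "n_down": sum(1 for c in calls if c.direction == "down"),
        "n_ambiguous": sum(1 for c in calls if c.direction == "ambiguous"),
        "all_genes": split(all_genes),
        "responsive": split(resp_genes),
        "non_responsive": split(non_resp),
    }
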