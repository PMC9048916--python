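"""Operating-characteristic benchmarks of the full pipeline.

Null calibration (zero injected effects: how often does the classifier stay
silent?) and parameter recovery (sensitivity and false-discovery proportion
against the generator's ground truth).  Both run the complete
simulate -> normalize -> test -> classify chain at the shipped study
conditions: ~80 genes, 3 replicates, 7 post-shift timepoints, default noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalize import normalize_scans
from .plastome import StudyDesign, assign_probes, default_annotation, default_probe_layout
from .simulate import NoiseModel, cold_shift_preset, simulate_study
from .stats import classify_cold_responsive, fold_changes


def _fixture():
    annotation = default_annotation()
    probes = assign_probes(default_probe_layout(annotation), annotation)
    return annotation, probes


def run_study(seed: int, effects=None, design: StudyDesign | None = None,
              noise: NoiseModel | None = None, pi0_method: str = "fixed_1"):
    """One simulated study through the classifier; returns (calls, truth)."""
    design = design or StudyDesign()
    annotation, probes = _fixture()
    if effects is None:
        effects = []
    elif effects == "cold_preset":
        effects = cold_shift_preset(probes)
    scans, truth = simulate_study(design, annotation, probes, effects, noise or NoiseModel(), seed)
    abundances, _, _, _ = normalize_scans(scans, probes)
    fc = fold_changes(abundances, design, pi0_method=pi0_method)
    calls = classify_cold_responsive(fc, design)
    return calls, truth


@dataclass
class NullCalibration:
    n_studies: int
    n_silent: int  # studies with zero cold-responsive calls
    calls_per_study: list[int]

    @property
    def fraction_silent(self) -> float:
        return self.n_silent / self.n_studies


def null_calibration(n_studies: int = 50, base_seed: int = 0) -> NullCalibration:
    """Zero-effect simulations: the classifier should call nothing."""
    counts = []
    for i in range(n_studies):
        calls, _ = run_study(base_seed + i, effects=None)
        counts.append(len(calls))
    return NullCalibration(n_studies, sum(1 for c in counts if c == 0), counts)


@dataclass
class PausingRecovery:
    site_sensitivity: float      # injected sites called with the right sign
    n_unexplained_calls: int     # calls not attributable to any injected local effect
    max_conservation_dev: float  # max |sum of within-ORF occupancy deltas|


def pausing_recovery(n_seeds: int = 10, base_seed: int = 5000) -> PausingRecovery:
    """Recovery of injected redistribution sites through the occupancy stage.

    Probes of genes carrying an injected splicing shift legitimately
    redistribute too (the downstream-exon share changes), so calls there
    count as explained.
    """
    from .pausing import call_redistributed_probes, occupancy_ratios, relative_occupancy

    design = StudyDesign()
    annotation, probes = _fixture()
    effects = cold_shift_preset(probes)
    hits, total, unexplained = 0, 0, 0
    max_dev = 0.0
    for i in range(n_seeds):
        scans, truth = simulate_study(design, annotation, probes, effects, NoiseModel(), base_seed + i)
        _, _, table, _ = normalize_scans(scans, probes)
        occ = relative_occupancy(table)
        ratios = occupancy_ratios(occ, design)
        calls, _ = call_redistributed_probes(ratios, design)
        site_dir = {
            pid: "up" if sub["true_log2_shift"].max() > 0 else "down"
            for pid, sub in truth.pausing.groupby("probe_id")
        }
        called = {c.probe_id: c for c in calls}
        total += len(site_dir)
        hits += sum(1 for pid, d in site_dir.items()
                    if pid in called and called[pid].direction == d)
        splicing_genes = set(truth.splicing.gene)
        unexplained += sum(1 for c in calls
                           if c.probe_id not in site_dir and c.gene not in splicing_genes)
        # conservation: occupancy deltas within a fully-paired ORF cancel
        piv = occ.pivot_table(
            index=["orf", "layer", "timepoint", "replicate", "probe_id"],
            columns="condition", values="occupancy",
        ).dropna()
        delta = (piv["acclimating"] - piv["control"]).groupby(
            ["orf", "layer", "timepoint", "replicate"]
        ).sum()
        n_pair = piv.groupby(["orf", "layer", "timepoint", "replicate"]).size()
        n_all = occ.groupby(["orf", "layer", "timepoint", "replicate"])["probe_id"].nunique()
        complete = delta[n_pair == n_all.reindex(n_pair.index)]
        if len(complete):
            max_dev = max(max_dev, float(np.abs(complete).max()))
    return PausingRecovery(hits / total if total else 0.0, unexplained, max_dev)


@dataclass
class RecoveryResult:
    sensitivity: float
    fdp: float
    per_seed_sensitivity: list[float]
    per_seed_fdp: list[float]


def parameter_recovery(n_seeds: int = 25, base_seed: int = 1000) -> RecoveryResult:
    """Recovery of the 13 injected cold-responsive genes, averaged over seeds."""
    sens, fdps = [], []
    for i in range(n_seeds):
        calls, truth = run_study(base_seed + i, effects="cold_preset")
        called = {c.gene for c in calls}
        true = truth.responsive_genes
        tp = len(called & true)
        sens.append(tp / len(true))
        fdps.append((len(called) - tp) / len(called) if called else 0.0)
    return RecoveryResult(
        float(np.mean(sens)), float(np.mean(fdps)), sens, fdps
    )
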