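"""Synthetic two-color tiling-array generator with ground truth.

Emulates the cold-shift hybridization experiment: for every (layer,
timepoint, replicate) one two-channel array carries the acclimating sample
in channel 635 and the paired control in channel 532; separate hybridizations
measure ribosome footprints and RNA.  The pre-shift baseline sample is
simulated as an array pair with both channels drawn from the control
process.

The signal model for a coding probe is multiplicative on the log2 scale:

    signal = gene_baseline * probe_affinity * effect(t)
             * 2^(hybridization noise) * 2^(channel noise)  + background

Injected effects come in three flavours: whole-ORF output/RNA trajectories,
probe-local occupancy shifts (redistribution: the ORF total is rescaled so
overall loading is preserved), and downstream-exon splicing shifts (likewise
compensated, mirroring the observation that splicing changes need not alter
whole-ORF output).  Every random draw descends from one master seed through
per-array substreams keyed by (layer, timepoint, replicate), so adding
arrays never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plastome import PlastomeAnnotation, Probe, StudyDesign, probe_frame

LOG2_15 = float(np.log2(1.5))

GPR_COLUMNS = ["Name", "F635 Median", "B635 Median", "F532 Median", "B532 Median", "Flags"]
FLAG_SATURATED = -100


@dataclass
class EffectSpec:
    """Injected perturbation for one gene.

    trajectory: per post-shift timepoint log2 effect (acclimating vs
    control) on the given layer ('footprint', 'rna' or 'both').
    pausing_sites: (probe_id, per-timepoint log2 local occupancy shift);
    shifts are compensated within the ORF so the total is preserved.
    splicing_shift: per-timepoint log2 change of the downstream-exon
    (exon >= 2) footprint share, also compensated within the ORF.
    """

    gene: str
    layer: str = "footprint"
    trajectory: tuple[float, ...] | None = None
    pausing_sites: tuple[tuple[str, tuple[float, ...]], ...] = ()
    splicing_shift: tuple[float, ...] | None = None

    def validate(self, n_timepoints: int) -> None:
        for name, traj in [("trajectory", self.trajectory), ("splicing_shift", self.splicing_shift)]:
            if traj is not None and len(traj) != n_timepoints:
                raise ValueError(f"{self.gene}: {name} length != {n_timepoints}")
        for pid, traj in self.pausing_sites:
            if len(traj) != n_timepoints:
                raise ValueError(f"{self.gene}: pausing trajectory for {pid} length != {n_timepoints}")
        if self.layer not in ("footprint", "rna", "both"):
            raise ValueError(f"{self.gene}: unknown layer {self.layer!r}")


@dataclass
class NoiseModel:
    """Stochastic components of the scanner/hybridization model.

    All *_sd parameters are log2-scale standard deviations except the
    additive channel background (raw counts).  ``hybridization_sd`` is a
    per-probe spot effect shared by both channels of one array (it cancels
    in within-array ratios, as on real two-color arrays); ``replicate_sd``
    is independent per channel.
    """

    baseline_log2_mean: float = 11.0
    baseline_log2_sd: float = 1.2
    probe_affinity_sd: float = 0.8
    background_mean: float = 60.0
    background_sd: float = 15.0
    hybridization_sd: float = 0.20
    replicate_sd: float = 0.10
    saturation_level: float = 65535.0

    def __post_init__(self) -> None:
        for f in ("baseline_log2_sd", "probe_affinity_sd", "background_sd", "hybridization_sd", "replicate_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.saturation_level <= self.background_mean:
            raise ValueError("saturation_level must exceed background_mean")


@dataclass
class ArrayScan:
    """One hybridization's raw per-probe two-channel scan."""

    layer: str
    timepoint: str
    replicate: int
    data: pd.DataFrame  # probe_id, f635, b635, f532, b532, flags

    def net(self, channel: str) -> pd.Series:
        return self.data[f"f{channel}"] - self.data[f"b{channel}"]


@dataclass
class TruthTable:
    """Ground truth of a simulated study."""

    effects: pd.DataFrame    # gene, timepoint, true_log2_output, true_log2_rna, true_log2_te
    responsive: pd.DataFrame  # gene, direction
    pausing: pd.DataFrame    # gene, probe_id, timepoint, true_log2_shift
    splicing: pd.DataFrame   # gene, timepoint, true_log2_shift

    @property
    def responsive_genes(self) -> set[str]:
        return set(self.responsive["gene"])


def _substream(seed: int, *key: object) -> np.random.Generator:
    """Stable per-key RNG substream derived from the master seed."""
    tag = zlib.crc32("|".join(str(k) for k in key).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _truth_qualifies(traj: np.ndarray, threshold_log2: float = LOG2_15,
                     min_total: int = 3, min_consec: int = 2) -> bool:
    """Apply the cold-responsive rule to a noise-free trajectory."""
    hits = np.abs(traj) >= threshold_log2
    if hits.sum() >= min_total:
        return True
    run = 0
    for h in hits:
        run = run + 1 if h else 0
        if run >= min_consec:
            return True
    return False


def simulate_study(
    design: StudyDesign,
    annotation: PlastomeAnnotation,
    probes: list[Probe],
    effects: list[EffectSpec],
    noise: NoiseModel,
    seed: int,
) -> tuple[list[ArrayScan], TruthTable]:
    """Simulate the full factorial study and return scans plus ground truth."""
    tp_labels = design.timepoint_labels
    n_tp = len(tp_labels)
    for eff in effects:
        eff.validate(n_tp)
        if eff.gene not in annotation:
            raise ValueError(f"effect gene {eff.gene!r} not in annotation")
    pdf = probe_frame(probes)
    probe_ids = pdf["probe_id"].to_numpy()
    id_to_row = {pid: i for i, pid in enumerate(probe_ids)}
    for eff in effects:
        for pid, _ in eff.pausing_sites:
            if pid not in id_to_row:
                raise ValueError(f"pausing site {pid!r} not in probe layout")
            if pdf.loc[id_to_row[pid], "orf"] != eff.gene:
                raise ValueError(f"pausing site {pid!r} is not a probe of {eff.gene}")

    n_probes = len(pdf)
    orf_of = pdf["orf"].to_numpy(dtype=object)
    exon_of = pdf["exon_index"].to_numpy()

    rng0 = _substream(seed, "baseline")
    gene_names = annotation.gene_names
    gene_baseline = {
        g: float(2.0 ** (noise.baseline_log2_mean + noise.baseline_log2_sd * rng0.standard_normal()))
        for g in gene_names
    }
    affinity = 2.0 ** (noise.probe_affinity_sd * rng0.standard_normal(n_probes))
    w0 = np.array([gene_baseline.get(o, 0.0) if o is not None else 0.0 for o in orf_of]) * affinity

    # pre-index effects per layer
    def _layer_effects(layer: str) -> list[EffectSpec]:
        return [e for e in effects if e.trajectory is not None and e.layer in (layer, "both")]

    fp_local = [e for e in effects if e.pausing_sites or e.splicing_shift is not None]

    def expected_weights(layer: str, t_index: int) -> np.ndarray:
        """Noise-free acclimating-channel probe weights at one timepoint."""
        w = w0.copy()
        for eff in _layer_effects(layer):
            mask = orf_of == eff.gene
            w[mask] *= 2.0 ** eff.trajectory[t_index]
        if layer == "footprint":
            for eff in fp_local:
                mask = orf_of == eff.gene
                if not mask.any():
                    continue
                total_before = w[mask].sum()
                m = np.ones(n_probes)
                if eff.splicing_shift is not None:
                    down = mask & (exon_of >= 2)
                    m[down] *= 2.0 ** eff.splicing_shift[t_index]
                for pid, traj in eff.pausing_sites:
                    m[id_to_row[pid]] *= 2.0 ** traj[t_index]
                w[mask] *= m[mask]
                total_after = w[mask].sum()
                if total_after > 0:
                    w[mask] *= total_before / total_after
        return w

    def render(rng: np.random.Generator, w635: np.ndarray, w532: np.ndarray) -> pd.DataFrame:
        h = 2.0 ** (noise.hybridization_sd * rng.standard_normal(n_probes))
        out = {}
        for ch, w in (("635", w635), ("532", w532)):
            c = 2.0 ** (noise.replicate_sd * rng.standard_normal(n_probes))
            b_true = np.clip(rng.normal(noise.background_mean, noise.background_sd, n_probes), 0, None)
            b_est = np.clip(rng.normal(noise.background_mean, noise.background_sd, n_probes), 0, None)
            f = w * h * c + b_true
            out[f"f{ch}"] = np.minimum(f, noise.saturation_level)
            out[f"b{ch}"] = b_est
            out[f"sat{ch}"] = f >= noise.saturation_level
        flags = np.where(out.pop("sat635") | out.pop("sat532"), FLAG_SATURATED, 0)
        return pd.DataFrame({"probe_id": probe_ids, **out, "flags": flags})

    scans: list[ArrayScan] = []
    for layer in design.layers:
        for rep in design.replicates:
            rng = _substream(seed, layer, design.baseline_label, rep)
            scans.append(ArrayScan(layer, design.baseline_label, rep, render(rng, w0, w0)))
        for t_index, tp in enumerate(tp_labels):
            w_acc = expected_weights(layer, t_index)
            for rep in design.replicates:
                rng = _substream(seed, layer, tp, rep)
                scans.append(ArrayScan(layer, tp, rep, render(rng, w_acc, w0)))

    truth = _build_truth(design, effects, n_tp)
    return scans, truth


def _build_truth(design: StudyDesign, effects: list[EffectSpec], n_tp: int) -> TruthTable:
    tp_labels = design.timepoint_labels
    out: dict[str, np.ndarray] = {}
    rna: dict[str, np.ndarray] = {}
    for eff in effects:
        if eff.trajectory is None:
            continue
        traj = np.asarray(eff.trajectory, dtype=float)
        if eff.layer in ("footprint", "both"):
            out[eff.gene] = out.get(eff.gene, np.zeros(n_tp)) + traj
        if eff.layer in ("rna", "both"):
            rna[eff.gene] = rna.get(eff.gene, np.zeros(n_tp)) + traj
    genes = sorted(set(out) | set(rna))
    rows = []
    resp = []
    for g in genes:
        o = out.get(g, np.zeros(n_tp))
        r = rna.get(g, np.zeros(n_tp))
        for i, tp in enumerate(tp_labels):
            rows.append((g, tp, o[i], r[i], o[i] - r[i]))
        if _truth_qualifies(o):
            qual = o[np.abs(o) >= LOG2_15]
            resp.append((g, "up" if qual.mean() > 0 else "down"))
    prow = [
        (eff.gene, pid, tp_labels[i], traj[i])
        for eff in effects
        for pid, traj in eff.pausing_sites
        for i in range(n_tp)
    ]
    srow = [
        (eff.gene, tp_labels[i], eff.splicing_shift[i])
        for eff in effects
        if eff.splicing_shift is not None
        for i in range(n_tp)
    ]
    return TruthTable(
        effects=pd.DataFrame(rows, columns=["gene", "timepoint", "true_log2_output", "true_log2_rna", "true_log2_te"]),
        responsive=pd.DataFrame(resp, columns=["gene", "direction"]),
        pausing=pd.DataFrame(prow, columns=["gene", "probe_id", "timepoint", "true_log2_shift"]),
        splicing=pd.DataFrame(srow, columns=["gene", "timepoint", "true_log2_shift"]),
    )


# ---------------------------------------------------------------------------
# GPR-dialect I/O
# ---------------------------------------------------------------------------

def write_gpr(scan: ArrayScan, path) -> None:
    """Write one scan as a GPR-dialect TSV (integer intensities)."""
    df = scan.data
    out = pd.DataFrame(
        {
            "Name": df["probe_id"],
            "F635 Median": np.rint(df["f635"]).astype(int),
            "B635 Median": np.rint(df["b635"]).astype(int),
            "F532 Median": np.rint(df["f532"]).astype(int),
            "B532 Median": np.rint(df["b532"]).astype(int),
            "Flags": df["flags"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_gpr(path, layer: str, timepoint: str, replicate: int) -> ArrayScan:
    df = pd.read_csv(path, sep="\t", dtype={"Name": str})
    missing = set(GPR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing GPR columns {sorted(missing)}")
    data = pd.DataFrame(
        {
            "probe_id": df["Name"],
            "f635": df["F635 Median"].astype(float),
            "b635": df["B635 Median"].astype(float),
            "f532": df["F532 Median"].astype(float),
            "b532": df["B532 Median"].astype(float),
            "flags": df["Flags"].astype(int),
        }
    )
    return ArrayScan(layer, timepoint, replicate, data)


# ---------------------------------------------------------------------------
# Cold-shift effect preset
# ---------------------------------------------------------------------------

#: translation-output trajectories (log2, acclimating vs control) for the
#: 13 cold-responsive genes: gradual onset, sustained response, psbA peaking
#: at four-fold induction and psbM showing the strongest repression.
COLD_RESPONSIVE_TRAJECTORIES: dict[str, tuple[float, ...]] = {
    "psbA": (0.3, 0.6, 1.0, 1.4, 1.8, 2.0, 2.0),
    "petL": (0.0, 0.3, 0.7, 1.0, 1.2, 1.3, 1.3),
    "ndhC": (0.0, 0.2, 0.5, 0.9, 1.0, 1.1, 1.0),
    "accD": (0.0, 0.0, 0.4, 0.9, 1.0, 1.0, 0.9),
    "psbM": (-0.3, -0.6, -1.0, -1.4, -1.7, -1.7, -1.6),
    "psbZ": (-0.2, -0.4, -0.8, -1.1, -1.2, -1.2, -1.1),
    "atpF": (0.0, -0.3, -0.6, -1.0, -1.1, -1.0, -1.0),
    "ndhA": (0.0, -0.2, -0.6, -1.0, -1.2, -1.2, -1.1),
    "ndhG": (0.0, -0.3, -0.7, -1.0, -1.0, -1.1, -1.0),
    "ndhI": (0.0, -0.2, -0.5, -0.9, -1.0, -1.0, -1.0),
    "petN": (0.0, -0.3, -0.6, -0.9, -1.0, -1.0, -0.9),
    "rps15": (0.0, -0.2, -0.5, -0.9, -1.0, -1.0, -1.0),
    "rpl22": (0.0, -0.3, -0.6, -0.9, -1.0, -1.0, -1.0),
}

# gene -> local log2 occupancy shift of one mid-ORF probe.  Sites sit in
# well-expressed reading frames with enough probes that the compensating
# within-ORF rescale does not swallow the injected shift.
PAUSING_PRESET: dict[str, tuple[float, ...]] = {
    "atpI": (0.0, 0.3, 0.8, 1.5, 1.5, 1.5, 1.5),
    "ycf2": (0.0, 0.2, 0.7, 1.5, 1.5, 1.5, 1.4),
    "psaB": (0.0, -0.3, -0.8, -1.8, -1.8, -1.8, -1.8),
}

SPLICING_PRESET: dict[str, tuple[float, ...]] = {
    "ndhA": (0.0, 0.0, 0.3, 0.7, 1.0, 1.1, 1.0),
    "clpP": (0.0, 0.0, -0.3, -0.6, -0.9, -1.0, -1.0),
}


def _middle_probe(pdf: pd.DataFrame, gene: str) -> str:
    sub = pdf[(pdf["orf"] == gene)].sort_values("start")
    if sub.empty:
        raise ValueError(f"no probes for {gene}")
    return str(sub["probe_id"].iloc[len(sub) // 2])


def cold_shift_preset(
    probes: list[Probe],
    include_pausing: bool = True,
    include_splicing: bool = True,
) -> list[EffectSpec]:
    """The shipped 13-gene cold-response effect set with local perturbations."""
    pdf = probe_frame(probes)
    specs = [
        EffectSpec(gene=g, layer="footprint", trajectory=traj)
        for g, traj in COLD_RESPONSIVE_TRAJECTORIES.items()
    ]
    by_gene = {s.gene: s for s in specs}
    if include_pausing:
        for gene, traj in PAUSING_PRESET.items():
            site = (_middle_probe(pdf, gene), traj)
            if gene in by_gene:
                by_gene[gene].pausing_sites = by_gene[gene].pausing_sites + (site,)
            else:
                specs.append(EffectSpec(gene=gene, pausing_sites=(site,)))
                by_gene[gene] = specs[-1]
    if include_splicing:
        for gene, traj in SPLICING_PRESET.items():
            if gene in by_gene:
                by_gene[gene].splicing_shift = traj
            else:
                specs.append(EffectSpec(gene=gene, splicing_shift=traj))
                by_gene[gene] = specs[-1]
    return specs
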