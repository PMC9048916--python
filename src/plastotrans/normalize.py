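"""Probe QC and the normalization cascade.

Fixed stage order: net signal (background subtraction with floor and
saturation exclusion) -> per-array global scaling of coding probes to the
grand mean -> within-ORF pooled-SD normalization per hybridization ->
ORF-level averaging.  Saturated probes are dropped entirely; background
probes are set to exactly zero and retained in ORF means.  A manifest of
per-stage exclusion counts accompanies every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plastome import Probe, probe_frame
from .simulate import ArrayScan

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_BACKGROUND = "background"
STATUS_SATURATED = "saturated"

DEFAULT_FLOOR = 100.0
DEFAULT_SATURATION = 65535.0

#: channel -> condition mapping (a dye swap flips it)
CHANNEL_CONDITIONS = {"635": "acclimating", "532": "control"}


@dataclass
class NormalizationManifest:
    """Per-stage bookkeeping of probe exclusions and scaling factors."""

    n_entries: int = 0
    n_saturated: int = 0
    n_background: int = 0
    array_scale_factors: dict[tuple, float] = field(default_factory=dict)
    constant_orfs: list[tuple] = field(default_factory=list)
    dropped_orfs: list[tuple] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "n_saturated": self.n_saturated,
            "n_background": self.n_background,
            "n_arrays_scaled": len(self.array_scale_factors),
            "n_constant_orfs": len(self.constant_orfs),
            "n_dropped_orfs": len(self.dropped_orfs),
        }


def net_signal(
    f: np.ndarray,
    b: np.ndarray,
    floor: float = DEFAULT_FLOOR,
    saturation_level: float = DEFAULT_SATURATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract one channel, applying floor and saturation QC.

    Returns (value, status): value = max(F-B, 0), set to exactly 0 with
    'background' status when F-B < floor; 'saturated' entries (F at or above
    the scanner ceiling) carry NaN and must not be used downstream.
    """
    f = np.asarray(f, dtype=float)
    b = np.asarray(b, dtype=float)
    net = np.maximum(f - b, 0.0)
    status = np.full(f.shape, STATUS_OK, dtype=object)
    bg = (f - b) < floor
    status[bg] = STATUS_BACKGROUND
    net[bg] = 0.0
    sat = f >= saturation_level
    status[sat] = STATUS_SATURATED
    net[sat] = np.nan
    return net, status


def build_signal_table(
    scans: list[ArrayScan],
    probes: list[Probe],
    floor: float = DEFAULT_FLOOR,
    saturation_level: float = DEFAULT_SATURATION,
    dye_swap: bool = False,
    manifest: NormalizationManifest | None = None,
) -> pd.DataFrame:
    """Long-format per-(probe, channel) net-signal table for all scans.

    Columns: probe_id, orf, exon_index, coding, layer, condition,
    timepoint, replicate, value, status.
    """
    pdf = probe_frame(probes).set_index("probe_id")
    chan_cond = dict(CHANNEL_CONDITIONS)
    if dye_swap:
        chan_cond = {"635": chan_cond["532"], "532": chan_cond["635"]}
    frames = []
    for scan in scans:
        ann = pdf.reindex(scan.data["probe_id"])
        for channel, condition in chan_cond.items():
            value, status = net_signal(
                scan.data[f"f{channel}"].to_numpy(),
                scan.data[f"b{channel}"].to_numpy(),
                floor=floor,
                saturation_level=saturation_level,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": scan.data["probe_id"].to_numpy(),
                        "orf": ann["orf"].to_numpy(),
                        "exon_index": ann["exon_index"].to_numpy(),
                        "coding": ann["orf"].notna().to_numpy() & ~ann["ambiguous"].to_numpy(),
                        "layer": scan.layer,
                        "condition": condition,
                        "timepoint": scan.timepoint,
                        "replicate": scan.replicate,
                        "value": value,
                        "status": status,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    if manifest is not None:
        manifest.n_entries = len(table)
        manifest.n_saturated = int((table["status"] == STATUS_SATURATED).sum())
        manifest.n_background = int((table["status"] == STATUS_BACKGROUND).sum())
    return table


_ARRAY_KEY = ["layer", "timepoint", "replicate"]


def global_scale(
    table: pd.DataFrame, manifest: NormalizationManifest | None = None
) -> pd.DataFrame:
    """Scale each array's valid coding-probe signals to the grand mean.

    Every hybridization's mean valid coding signal is brought to the grand
    mean of valid coding signals pooled over all arrays, making arrays
    comparable while preserving the overall signal level.
    """
    table = table.copy()
    valid = (table["status"] != STATUS_SATURATED) & table["coding"]
    sub = table.loc[valid]
    if sub.empty:
        raise ValueError("no valid coding-probe signals in any array")
    grand_mean = sub["value"].mean()
    array_means = sub.groupby(_ARRAY_KEY)["value"].mean()
    n_arrays = table[_ARRAY_KEY].drop_duplicates()
    for key in n_arrays.itertuples(index=False):
        k = tuple(key)
        if k not in array_means.index or array_means.loc[k] <= 0:
            raise ValueError(f"array {k} has no valid coding-probe signal")
    factors = grand_mean / array_means
    keys = pd.MultiIndex.from_frame(table[_ARRAY_KEY])
    table["value"] = table["value"] * factors.reindex(keys).to_numpy()
    if manifest is not None:
        manifest.array_scale_factors = {k: float(v) for k, v in factors.items()}
    return table


_HYB_ORF_KEY = ["layer", "timepoint", "replicate", "orf"]


def within_orf_sd_normalize(
    table: pd.DataFrame, manifest: NormalizationManifest | None = None
) -> pd.DataFrame:
    """Divide each ORF's probe signals by their pooled per-hybridization SD.

    Both channels of one hybridization are pooled, equalizing the
    within-ORF variance across replicates (the cascade's answer to
    labeling/hybridization efficiency differences).  ORFs whose pooled SD is
    zero (or with fewer than two valid values) pass through unscaled and are
    flagged in the manifest.
    """
    table = table.copy()
    valid = (table["status"] != STATUS_SATURATED) & table["orf"].notna()
    sub = table.loc[valid]
    sd = sub.groupby(_HYB_ORF_KEY)["value"].agg(["std", "count"])
    usable = (sd["count"] >= 2) & (sd["std"] > 0)
    scale = pd.Series(np.where(usable, sd["std"], 1.0), index=sd.index)
    keys = pd.MultiIndex.from_frame(table[_HYB_ORF_KEY])
    factors = scale.reindex(keys).to_numpy()
    factors = np.where(np.isnan(factors), 1.0, factors)
    mask = valid.to_numpy()
    table.loc[mask, "value"] = table.loc[mask, "value"] / factors[mask]
    if manifest is not None:
        manifest.constant_orfs = [tuple(k) for k in sd.index[~usable]]
        if manifest.constant_orfs:
            logger.warning("within-ORF SD normalization: %d constant/underpowered ORF groups passed through unscaled", len(manifest.constant_orfs))
    return table


def orf_abundance(
    table: pd.DataFrame,
    min_probes: int = 2,
    by_exon: bool = False,
    manifest: NormalizationManifest | None = None,
) -> pd.DataFrame:
    """Average normalized probe values per ORF (optionally per exon).

    Saturated probes are excluded; background zeros are included in the
    mean.  Entries supported by fewer than ``min_probes`` valid probes are
    flagged low-support, not dropped.
    """
    group_cols = (["orf", "exon_index"] if by_exon else ["orf"]) + ["layer", "condition", "timepoint", "replicate"]
    valid = (table["status"] != STATUS_SATURATED) & table["orf"].notna()
    sub = table.loc[valid]
    out = (
        sub.groupby(group_cols, dropna=False)["value"]
        .agg(abundance="mean", n_valid="count")
        .reset_index()
    )
    out["low_support"] = out["n_valid"] < min_probes
    if manifest is not None and not by_exon:
        all_keys = table.loc[table["orf"].notna(), group_cols].drop_duplicates()
        merged = all_keys.merge(out[group_cols], how="left", indicator=True, on=group_cols)
        dropped = merged.loc[merged["_merge"] == "left_only", group_cols]
        manifest.dropped_orfs = [tuple(r) for r in dropped.itertuples(index=False)]
        if manifest.dropped_orfs:
            logger.warning("%d ORF entries had all probes saturated and were dropped", len(manifest.dropped_orfs))
    return out


def normalize_scans(
    scans: list[ArrayScan],
    probes: list[Probe],
    floor: float = DEFAULT_FLOOR,
    saturation_level: float = DEFAULT_SATURATION,
    min_probes: int = 2,
    dye_swap: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, NormalizationManifest]:
    """Run the full cascade in its fixed order.

    Returns (orf_abundance, exon_abundance, normalized signal table,
    manifest).
    """
    manifest = NormalizationManifest()
    table = build_signal_table(
        scans, probes, floor=floor, saturation_level=saturation_level,
        dye_swap=dye_swap, manifest=manifest,
    )
    table = global_scale(table, manifest=manifest)
    table = within_orf_sd_normalize(table, manifest=manifest)
    abundances = orf_abundance(table, min_probes=min_probes, manifest=manifest)
    exon_abundances = orf_abundance(table, min_probes=1, by_exon=True)
    return abundances, exon_abundances, table, manifest
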