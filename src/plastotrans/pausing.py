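"""Local ribosome-occupancy redistribution (pausing) analysis.

Each probe's footprint signal is expressed as a share of its reading
frame's total (relative local occupancy), so whole-ORF loading changes
cancel and only redistribution along the transcript remains.  Per probe and
timepoint the acclimating/control occupancy ratio is summarized by a
parametric Gaussian density over all coding probes, and probes whose
occupancy rises (or falls) more than two-fold with statistical significance
at two consecutive timepoints are called redistributed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .normalize import STATUS_SATURATED
from .plastome import StudyDesign
from .stats import storey_qvalues


def _pooled_z_pvalues(d: np.ndarray, n_fin: np.ndarray) -> np.ndarray:
    """Two-sided p for per-probe mean log2 ratios with family-pooled variance.

    d is (probes, replicates) of paired log2 ratios; the per-replicate
    variance is pooled over all probes of the family (one layer/timepoint)
    and the resulting z statistic is referred to the normal distribution.
    """
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dd = np.where(np.isfinite(d), d, np.nan)
        m = np.nanmean(dd, axis=1)
        s2 = np.nanvar(dd, axis=1, ddof=1)
    usable = n_fin >= 2
    if not np.any(usable & np.isfinite(s2)):
        return np.full(len(d), np.nan)
    pooled = np.nanmean(s2[usable])
    if pooled == 0:
        p = np.where(m == 0, 1.0, 0.0)
    else:
        z = m / np.sqrt(pooled / np.maximum(n_fin, 1))
        p = 2.0 * norm.sf(np.abs(z))
    return np.where(usable, p, np.nan)

logger = logging.getLogger(__name__)

_GROUP = ["orf", "layer", "condition", "timepoint", "replicate"]


def relative_occupancy(table: pd.DataFrame, min_probes: int = 2) -> pd.DataFrame:
    """Within-ORF relative occupancy of every valid coding probe.

    Input is the normalized signal table; occupancies within one
    (ORF, layer, condition, timepoint, replicate) group sum to one.  Groups
    with a zero total or fewer than ``min_probes`` valid probes are skipped
    and logged.  Scale-invariant by construction.
    """
    valid = (table["status"] != STATUS_SATURATED) & table["orf"].notna() & table["coding"]
    sub = table.loc[valid, _GROUP + ["probe_id", "value"]].copy()
    g = sub.groupby(_GROUP)["value"]
    total = g.transform("sum")
    count = g.transform("count")
    ok = (total > 0) & (count >= min_probes)
    n_skipped = sub.loc[~ok, _GROUP].drop_duplicates().shape[0]
    if n_skipped:
        logger.warning("relative_occupancy: %d ORF groups skipped (zero total or < %d probes)", n_skipped, min_probes)
    sub = sub.loc[ok].copy()
    sub["occupancy"] = sub["value"] / total[ok]
    return sub.drop(columns="value").reset_index(drop=True)


def occupancy_ratios(
    occ: pd.DataFrame,
    design: StudyDesign,
    pi0_method: str = "fixed_1",
) -> pd.DataFrame:
    """Per-(probe, layer, timepoint) acclimating/control occupancy contrast.

    Returns replicate-mean log2 ratios with p-values from a pooled-variance
    z test on the paired per-replicate log2 ratios (the per-probe variance
    is pooled across the whole probe family at one timepoint: with three
    replicates a per-probe Student t cannot survive correction over
    hundreds of probes, while replicate scatter is well shared across
    probes), and Storey q-values per (layer, timepoint) family.  Replicates
    where either condition's occupancy is zero (background probes) are
    dropped from the ratio; probes need >= 2 informative replicates.
    """
    rows = []
    tps = [design.baseline_label] + design.timepoint_labels
    for layer in design.layers:
        sl = occ[occ["layer"] == layer]
        if sl.empty:
            continue
        piv = sl.pivot_table(
            index=["probe_id", "orf", "timepoint"],
            columns=["condition", "replicate"],
            values="occupancy",
            aggfunc="first",
        )
        full_cols = pd.MultiIndex.from_product([list(design.conditions), design.replicates])
        piv = piv.reindex(columns=full_cols)
        vals = piv.to_numpy(dtype=float)
        vals = np.where(np.isfinite(vals) & (vals <= 0), np.nan, vals)
        n_rep = design.n_replicates
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = np.log2(vals[:, :n_rep])
            c = np.log2(vals[:, n_rep:])
            d = a - c
            n_fin = np.sum(np.isfinite(d), axis=1)
            mean_ratio = np.where(n_fin >= 2, np.nanmean(np.where(np.isfinite(d), d, np.nan), axis=1), np.nan)
        meta = piv.index.to_frame(index=False)
        df_l = pd.DataFrame(
            {
                "probe_id": meta["probe_id"],
                "orf": meta["orf"],
                "layer": layer,
                "timepoint": meta["timepoint"],
                "mean_log2_ratio": mean_ratio,
                "n_informative": n_fin,
            }
        )
        p = np.full(len(df_l), np.nan)
        for tp in tps:
            sel = (df_l["timepoint"] == tp).to_numpy()
            if sel.any():
                p[sel] = _pooled_z_pvalues(d[sel], n_fin[sel])
        df_l["p"] = p
        rows.append(df_l)
    out = pd.concat(rows, ignore_index=True)
    out["q"] = np.nan
    for layer in design.layers:
        for tp in tps:
            sel = ((out["layer"] == layer) & (out["timepoint"] == tp)).to_numpy()
            if sel.any():
                out.loc[sel, "q"] = storey_qvalues(out.loc[sel, "p"].to_numpy(), pi0_method=pi0_method)
    return out


@dataclass
class DensitySummary:
    """Parametric Gaussian summary of one timepoint's log2 occupancy ratios."""

    mu: float
    sigma: float
    mass_within_1sd: float  # Gaussian mass in [mu - sigma, mu + sigma]
    n: int
    degenerate: bool


def occupancy_ratio_density(ratios) -> DensitySummary:
    """Fit the Gaussian density summary to coding-probe log2 ratios.

    The summary is the analytic normal density with the sample mean and SD;
    its mass within one SD of the mean (68.27%) is evaluated from the
    Gaussian CDF rather than asserted.
    """
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    if len(r) < 10:
        raise ValueError("need >= 10 ratios for a density summary")
    mu = float(np.mean(r))
    sigma = float(np.std(r, ddof=1))
    if sigma == 0:
        logger.warning("degenerate occupancy-ratio density (sigma = 0)")
        return DensitySummary(mu, 0.0, float("nan"), len(r), True)
    mass = float(norm.cdf(mu + sigma, mu, sigma) - norm.cdf(mu - sigma, mu, sigma))
    return DensitySummary(mu, sigma, mass, len(r), False)


def density_summaries(ratios: pd.DataFrame, layer: str = "footprint") -> pd.DataFrame:
    """One Gaussian summary per timepoint for the given layer."""
    rows = []
    for tp, sub in ratios[ratios["layer"] == layer].groupby("timepoint", sort=False):
        d = occupancy_ratio_density(sub["mean_log2_ratio"])
        rows.append((tp, d.mu, d.sigma, d.mass_within_1sd, d.n, d.degenerate))
    return pd.DataFrame(rows, columns=["timepoint", "mu", "sigma", "mass_within_1sd", "n", "degenerate"])


@dataclass
class RedistributionCall:
    probe_id: str
    gene: str
    direction: str  # up / down
    timepoints: tuple[str, ...]


def call_redistributed_probes(
    ratios: pd.DataFrame,
    design: StudyDesign,
    fold: float = 2.0,
    q_max: float = 0.1,
    min_consec: int = 2,
    layer: str = "footprint",
) -> tuple[list[RedistributionCall], pd.DataFrame]:
    """Flag probes with sustained local occupancy shifts.

    A probe is called when |log2 ratio| exceeds log2(fold) with q < q_max
    at >= min_consec consecutive post-shift timepoints, all in the same
    direction.  Returns (probe calls, per-gene rollup by direction).
    """
    log_thr = np.log2(fold)
    tps = design.timepoint_labels
    calls: list[RedistributionCall] = []
    sub = ratios[(ratios["layer"] == layer) & (ratios["timepoint"].isin(tps))]
    for (pid, gene), grp in sub.groupby(["probe_id", "orf"], sort=True):
        grp = grp.set_index("timepoint").reindex(tps)
        v = grp["mean_log2_ratio"].to_numpy(dtype=float)
        q = grp["q"].to_numpy(dtype=float)
        for direction, hit in (
            ("up", np.isfinite(v) & np.isfinite(q) & (v > log_thr) & (q < q_max)),
            ("down", np.isfinite(v) & np.isfinite(q) & (v < -log_thr) & (q < q_max)),
        ):
            run = best_run = 0
            for h in hit:
                run = run + 1 if h else 0
                best_run = max(best_run, run)
            if best_run >= min_consec:
                calls.append(
                    RedistributionCall(str(pid), str(gene), direction, tuple(np.array(tps)[hit]))
                )
    rollup = (
        pd.DataFrame(
            {"gene": [c.gene for c in calls], "direction": [c.direction for c in calls]}
        )
        .groupby(["gene", "direction"])
        .size()
        .reset_index(name="n_probes")
        if calls
        else pd.DataFrame(columns=["gene", "direction", "n_probes"])
    )
    return calls, rollup
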