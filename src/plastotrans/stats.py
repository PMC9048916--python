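"""Fold-change inference and cold-response statistics.

Per reading frame and timepoint the pipeline reports three coupled log2
fold changes, each first normalized to the pre-shift baseline within
replicate and then contrasted between conditions:

    log2FC_output = mean_r log2[(FP_acc(t)/FP_acc(0)) / (FP_con(t)/FP_con(0))]
    log2FC_rna    = the same on the RNA layer
    log2FC_te     = log2FC_output - log2FC_rna   (identity of ratios)

Significance defaults to the paired Student t test of the per-replicate
log2 acclimating/control ratios against zero (the two conditions share one
hybridization, so the within-ORF SD-normalization factor cancels exactly in
the pair); the unpaired equal-variance two-sample test is selectable.
Storey q-values are computed per (measure, timepoint) family across genes.
A gene is called cold-responsive when its translation output changes more
than 1.5-fold with q below 0.1 at two consecutive or three total post-shift
timepoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plastome import PlastomeAnnotation, StudyDesign

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# t test and q-values
# ---------------------------------------------------------------------------

def ttest_two_sided(group_a, group_b, equal_var: bool = True) -> float:
    """Two-sided two-sample Student t test (equal variance by default).

    Degenerate convention: with zero pooled variance the p-value is 1 for
    equal means and 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    p = _ttest_nd(a[None, :], b[None, :], equal_var=equal_var)[0]
    return float(p)


def _ttest_nd(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> np.ndarray:
    """Vectorized two-sided t test along the last axis, NaN-aware.

    Rows with fewer than two finite values in either group yield NaN.
    """
    na = np.sum(np.isfinite(a), axis=-1)
    nb = np.sum(np.isfinite(b), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=-1)
        mb = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=-1)
        va = np.nanvar(np.where(np.isfinite(a), a, np.nan), axis=-1, ddof=1)
        vb = np.nanvar(np.where(np.isfinite(b), b, np.nan), axis=-1, ddof=1)
        if equal_var:
            df = na + nb - 2
            sp2 = ((na - 1) * va + (nb - 1) * vb) / np.where(df > 0, df, 1)
            se2 = sp2 * (1.0 / na + 1.0 / nb)
        else:
            se2 = va / na + vb / nb
            num = se2**2
            den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            df = np.where(den > 0, num / den, na + nb - 2)
        t = (ma - mb) / np.sqrt(se2)
        p = 2.0 * sps.t.sf(np.abs(t), np.where(df > 0, df, 1))
    zero_var = se2 == 0
    p = np.where(zero_var & (ma == mb), 1.0, p)
    p = np.where(zero_var & (ma != mb), 0.0, p)
    p = np.where((na < 2) | (nb < 2), np.nan, p)
    return p


def ttest_one_sample(values, popmean: float = 0.0) -> float:
    """Two-sided one-sample Student t test (used for paired contrasts).

    Same degenerate convention as the two-sample test: zero variance gives
    p = 1 when the mean equals ``popmean`` and p = 0 otherwise.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    return float(_ttest_1samp_nd(v[None, :] - popmean)[0])


def _ttest_1samp_nd(d: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t test against 0 along the last axis, NaN-aware."""
    n = np.sum(np.isfinite(d), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(np.where(np.isfinite(d), d, np.nan), axis=-1)
        v = np.nanvar(np.where(np.isfinite(d), d, np.nan), axis=-1, ddof=1)
        t = m / np.sqrt(v / n)
        p = 2.0 * sps.t.sf(np.abs(t), np.where(n > 1, n - 1, 1))
    p = np.where((v == 0) & (m == 0), 1.0, p)
    p = np.where((v == 0) & (m != 0), 0.0, p)
    p = np.where(n < 2, np.nan, p)
    return p


DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.91, 0.05), 2)


def estimate_pi0(pvals, lambda_grid=None, method: str = "smoother") -> float:
    """Estimate the null proportion pi0 from the p-value family.

    'smoother': cubic-polynomial smooth of pi0(lambda) evaluated at the
    largest lambda; 'fixed': single lambda = 0.5; 'fixed_1': pi0 = 1
    (Benjamini-Hochberg-equivalent, conservative).
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if method == "fixed_1":
        return 1.0
    if len(p) == 0:
        return 1.0
    m = len(p)
    if method == "fixed":
        pi0 = np.sum(p > 0.5) / (m * 0.5)
    elif method == "smoother":
        grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
        pi0_l = np.array([np.sum(p > lam) / (m * (1.0 - lam)) for lam in grid])
        coef = np.polyfit(grid, pi0_l, deg=3)
        pi0 = float(np.polyval(coef, grid.max()))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    if pi0 > 1.0:
        logger.warning("pi0 estimate %.3f > 1, clipped to 1", pi0)
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(pvals, lambda_grid=None, pi0_method: str = "fixed_1") -> np.ndarray:
    """Storey q-values; with pi0 = 1 this reduces exactly to BH adjusted p.

    NaN p-values yield NaN q-values and do not count toward the family
    size.  q(i) = min_{j>=i} pi0 * m * p(j) / j on the sorted family.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any(np.isfinite(p)) and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    ps = p[mask]
    m = len(ps)
    if m == 0:
        return q
    pi0 = estimate_pi0(ps, lambda_grid, pi0_method)
    order = np.argsort(ps, kind="mergesort")
    ranked = pi0 * m * ps[order] / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[mask] = out
    return q


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

MEASURES = ("output", "rna", "te")


def _abundance_array(
    abundances: pd.DataFrame, design: StudyDesign, orfs: list[str]
) -> np.ndarray:
    """(orf, layer, condition, baseline+timepoints, replicate) array."""
    tps = [design.baseline_label] + design.timepoint_labels
    idx = pd.MultiIndex.from_product(
        [orfs, list(design.layers), list(design.conditions), tps, design.replicates],
        names=["orf", "layer", "condition", "timepoint", "replicate"],
    )
    s = abundances.set_index(["orf", "layer", "condition", "timepoint", "replicate"])["abundance"]
    s = s[~s.index.duplicated()]
    vals = s.reindex(idx).to_numpy()
    return vals.reshape(
        len(orfs), len(design.layers), len(design.conditions), len(tps), design.n_replicates
    )


def fold_changes(
    abundances: pd.DataFrame,
    design: StudyDesign,
    pi0_method: str = "fixed_1",
    pseudo_floor: bool = True,
    test_mode: str = "paired",
) -> pd.DataFrame:
    """Per-(orf, timepoint) log2 fold changes with p and Storey q.

    Abundances are first normalized to the 0-day baseline within replicate;
    zero abundances are replaced (flagged in the log) by half the smallest
    positive abundance of the same layer before taking ratios.  Missing
    baselines propagate as missing values.

    test_mode 'paired' (default) tests the per-replicate log2 ratio
    (acclimating vs control within one hybridization) against zero, which
    cancels the within-ORF SD-normalization factor shared by both channels;
    'two_sample' contrasts the acclimating and control baseline-normalized
    groups directly.
    """
    orfs = sorted(abundances["orf"].dropna().unique())
    X = _abundance_array(abundances, design, orfs)
    layers = list(design.layers)
    conds = list(design.conditions)
    i_fp, i_rna = layers.index("footprint"), layers.index("rna")
    i_acc, i_con = conds.index("acclimating"), conds.index("control")

    X = X.astype(float)
    if pseudo_floor:
        for li in range(len(layers)):
            sl = X[:, li]
            pos = sl[np.isfinite(sl) & (sl > 0)]
            if pos.size:
                floor = 0.5 * pos.min()
                n_floored = int(np.sum(np.isfinite(sl) & (sl <= 0)))
                if n_floored:
                    logger.info("layer %s: %d zero abundances set to pseudo-floor %.4g", layers[li], n_floored, floor)
                X[:, li] = np.where(np.isfinite(sl) & (sl <= 0), floor, sl)
    else:
        X = np.where(X <= 0, np.nan, X)

    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.log2(X[:, :, :, 1:, :] / X[:, :, :, [0], :])  # vs baseline, per replicate

    la_fp, lc_fp = L[:, i_fp, i_acc], L[:, i_fp, i_con]
    la_rna, lc_rna = L[:, i_rna, i_acc], L[:, i_rna, i_con]
    lte_a = la_fp - la_rna
    lte_c = lc_fp - lc_rna

    def _fc(a, c):
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(a - c, axis=-1)

    fc_out = _fc(la_fp, lc_fp)
    fc_rna = _fc(la_rna, lc_rna)
    fc_te = fc_out - fc_rna
    if test_mode == "paired":
        p_out = _ttest_1samp_nd(la_fp - lc_fp)
        p_rna = _ttest_1samp_nd(la_rna - lc_rna)
        p_te = _ttest_1samp_nd(lte_a - lte_c)
    elif test_mode == "two_sample":
        p_out = _ttest_nd(la_fp, lc_fp)
        p_rna = _ttest_nd(la_rna, lc_rna)
        p_te = _ttest_nd(lte_a, lte_c)
    else:
        raise ValueError(f"unknown test_mode {test_mode!r}")

    tps = design.timepoint_labels
    rec = {
        "orf": np.repeat(orfs, len(tps)),
        "timepoint": np.tile(tps, len(orfs)),
        "log2fc_output": fc_out.ravel(),
        "log2fc_rna": fc_rna.ravel(),
        "log2fc_te": fc_te.ravel(),
        "p_output": p_out.ravel(),
        "p_rna": p_rna.ravel(),
        "p_te": p_te.ravel(),
    }
    fc = pd.DataFrame(rec)
    for meas in MEASURES:
        q = np.full(len(fc), np.nan)
        for tp in tps:
            sel = (fc["timepoint"] == tp).to_numpy()
            q[sel] = storey_qvalues(fc.loc[sel, f"p_{meas}"].to_numpy(), pi0_method=pi0_method)
        fc[f"q_{meas}"] = q
    return fc


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ResponseCall:
    """One cold-responsive gene call."""

    gene: str
    direction: str  # up / down / ambiguous
    significant_timepoints: tuple[str, ...]
    qualifying_rule: str  # consecutive2 / total3


def _max_run(mask: np.ndarray) -> int:
    run = best = 0
    for h in mask:
        run = run + 1 if h else 0
        best = max(best, run)
    return best


def classify_cold_responsive(
    fc: pd.DataFrame,
    design: StudyDesign,
    threshold: float = 1.5,
    q_max: float = 0.1,
    min_total: int = 3,
    min_consec: int = 2,
    measure: str = "output",
) -> list[ResponseCall]:
    """Apply the cold-responsive rule to the fold-change table.

    A timepoint qualifies when |log2FC| >= log2(threshold) and q < q_max;
    a gene is called when qualifying points number >= min_total in total or
    >= min_consec consecutively.  The 0-day baseline is never a qualifying
    point (it is not part of the table).
    """
    log_thr = np.log2(threshold)
    tps = design.timepoint_labels
    calls: list[ResponseCall] = []
    for gene, sub in fc.groupby("orf", sort=True):
        sub = sub.set_index("timepoint").reindex(tps)
        vals = sub[f"log2fc_{measure}"].to_numpy(dtype=float)
        qs = sub[f"q_{measure}"].to_numpy(dtype=float)
        hits = np.isfinite(vals) & np.isfinite(qs) & (np.abs(vals) >= log_thr) & (qs < q_max)
        n_total = int(hits.sum())
        run = _max_run(hits)
        if run >= min_consec or n_total >= min_total:
            qual_vals = vals[hits]
            signs = set(np.sign(qual_vals[qual_vals != 0]))
            if signs == {1.0}:
                direction = "up"
            elif signs == {-1.0}:
                direction = "down"
            else:
                direction = "ambiguous"
            rule = "consecutive2" if run >= min_consec else "total3"
            calls.append(
                ResponseCall(
                    gene=str(gene),
                    direction=direction,
                    significant_timepoints=tuple(np.array(tps)[hits]),
                    qualifying_rule=rule,
                )
            )
    return calls


def calls_frame(calls: list[ResponseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "direction": [c.direction for c in calls],
            "significant_timepoints": [",".join(c.significant_timepoints) for c in calls],
            "qualifying_rule": [c.qualifying_rule for c in calls],
        }
    )


@dataclass
class PercentileThresholds:
    low_cut: float
    high_cut: float
    degenerate: bool


def percentile_thresholds(values, top_frac: float = 0.10) -> PercentileThresholds:
    """Empirical bottom/top fold-change cutoffs over all genes x timepoints.

    Reported alongside the fixed 1.5-fold threshold: the top and bottom
    deciles of pooled log2 fold changes correspond approximately to the
    1.5-fold gate on real data.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 10:
        raise ValueError("need >= 10 values for percentile thresholds")
    low = float(np.quantile(v, top_frac))
    high = float(np.quantile(v, 1.0 - top_frac))
    degenerate = low == high
    if degenerate:
        logger.warning("degenerate percentile thresholds (all values equal?)")
    return PercentileThresholds(low, high, degenerate)


# ---------------------------------------------------------------------------
# splicing efficiency
# ---------------------------------------------------------------------------

def splicing_efficiency(
    exon_abundances: pd.DataFrame,
    annotation: PlastomeAnnotation,
    design: StudyDesign,
    min_exon_len: int = 10,
    pi0_method: str = "fixed_1",
    layer: str = "footprint",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Downstream/upstream exon footprint ratios for intron-containing genes.

    For each adjacent exon pair the statistic is the log2 ratio of
    (downstream/upstream) exon abundance in acclimating over control plants
    at the same timepoint.  Genes whose upstream exon is shorter than
    ``min_exon_len`` nt are excluded (their translation output cannot be
    quantified reliably); exon pairs without probes are reported missing.
    Returns (table, excluded list of (gene, reason)).
    """
    ab = exon_abundances[exon_abundances["layer"] == layer]
    key = ["orf", "exon_index", "condition", "timepoint", "replicate"]
    s = ab.set_index(key)["abundance"]
    s = s[~s.index.duplicated()]
    pos = s[s > 0]
    floor = 0.5 * pos.min() if len(pos) else np.nan

    def get(gene, exon, cond, tp):
        out = np.full(design.n_replicates, np.nan)
        for i, r in enumerate(design.replicates):
            try:
                v = s.loc[(gene, exon, cond, tp, r)]
            except KeyError:
                continue
            out[i] = floor if (np.isfinite(v) and v <= 0) else v
        return out

    rows = []
    excluded: list[tuple[str, str]] = []
    for orf in annotation.intron_containing():
        exon_idx = sorted(i for _, _, i in orf.exons)
        for up, down in zip(exon_idx, exon_idx[1:]):
            up_len = orf.exon_length(up)
            if up_len < min_exon_len:
                excluded.append((orf.name, f"upstream exon {up} only {up_len} nt"))
                continue
            for tp in design.timepoint_labels:
                ua, da = get(orf.name, up, "acclimating", tp), get(orf.name, down, "acclimating", tp)
                uc, dc = get(orf.name, up, "control", tp), get(orf.name, down, "control", tp)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ra = np.log2(da / ua)
                    rc = np.log2(dc / uc)
                d = ra - rc  # paired within hybridization
                if np.sum(np.isfinite(d)) < 2:
                    continue
                rows.append(
                    {
                        "gene": orf.name,
                        "exon_pair": f"{down}/{up}",
                        "timepoint": tp,
                        "log2_ratio": float(np.nanmean(d)),
                        "p": float(_ttest_1samp_nd(d[None, :])[0]),
                    }
                )
    table = pd.DataFrame(rows, columns=["gene", "exon_pair", "timepoint", "log2_ratio", "p"])
    # genes excluded by the short-exon rule must not appear at all
    bad = {g for g, _ in excluded}
    table = table[~table["gene"].isin(bad)].reset_index(drop=True)
    if len(table):
        q = np.full(len(table), np.nan)
        for tp in design.timepoint_labels:
            sel = (table["timepoint"] == tp).to_numpy()
            if sel.any():
                q[sel] = storey_qvalues(table.loc[sel, "p"].to_numpy(), pi0_method=pi0_method)
        table["q"] = q
    else:
        table["q"] = []
    return table, excluded


# ---------------------------------------------------------------------------
# polysome / monosome quantification
# ---------------------------------------------------------------------------

def polysome_monosome_ratio(
    fraction_signals, monosome_fractions, polysome_fractions
) -> float:
    """Sum-normalized polysome over monosome signal of one gradient.

    Fraction indices are 0-based positions in the signal vector; the two
    sets must be disjoint and non-empty.
    """
    sig = np.asarray(fraction_signals, dtype=float)
    mono = sorted(set(monosome_fractions))
    poly = sorted(set(polysome_fractions))
    if not mono or not poly:
        raise ValueError("monosome and polysome fraction sets must be non-empty")
    if set(mono) & set(poly):
        raise ValueError("monosome and polysome fraction sets overlap")
    total = sig.sum()
    if total <= 0:
        raise ValueError("gradient signal sums to zero")
    s = sig / total
    mono_sum = s[mono].sum()
    if mono_sum == 0:
        raise ValueError("monosome signal is zero; ratio undefined")
    return float(s[poly].sum() / mono_sum)


def relative_translation_activity(
    acclimating_signals, control_signals, monosome_fractions, polysome_fractions
) -> float:
    """Cold-to-control ratio of polysome/monosome ratios."""
    ra = polysome_monosome_ratio(acclimating_signals, monosome_fractions, polysome_fractions)
    rc = polysome_monosome_ratio(control_signals, monosome_fractions, polysome_fractions)
    return float(ra / rc)
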