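"""qPCR genome-copy-number math.

Cycle thresholds by the second-derivative-maximum criterion, amplification
efficiencies from serial-dilution standard curves, and efficiency-corrected
relative quantification against a nuclear reference (18S rDNA in the cold
study), reported as log2 fold change versus a matched baseline sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.signal import savgol_filter
from scipy.stats import linregress


class NoAmplificationError(ValueError):
    """Curve shows no sigmoidal amplification."""


@dataclass
class AmplificationCurve:
    cycle: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.cycle = np.asarray(self.cycle, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.cycle) < 10:
            raise ValueError("amplification curve needs >= 10 cycles")
        if len(self.cycle) != len(self.fluorescence):
            raise ValueError("cycle/fluorescence length mismatch")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")
        if np.any(np.diff(self.cycle) <= 0):
            raise ValueError("cycles must be strictly increasing")


@dataclass
class DilutionSeries:
    log10_dilution: np.ndarray
    ct: np.ndarray
    primer_pair: str = ""

    def __post_init__(self) -> None:
        self.log10_dilution = np.asarray(self.log10_dilution, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if len(self.log10_dilution) < 3:
            raise ValueError("dilution series needs >= 3 points")
        d = np.diff(self.log10_dilution)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("dilutions must be strictly ordered")


def ct_second_derivative_max(
    curve: AmplificationCurve, smoothing_window: int = 5
) -> float:
    """Fractional-cycle Ct at the maximum curvature of the rise.

    The curve is smoothed with a Savitzky-style local-polynomial filter
    (window in cycles, order 4), interpolated with a quintic spline, and the
    spline's second derivative is maximized on a dense (0.001-cycle) grid
    restricted to the rising flank (left of the maximum-slope cycle).
    """
    c, f = curve.cycle, curve.fluorescence
    baseline = np.median(f[:5])
    amplitude = f.max() - f.min()
    if f.max() <= 5.0 * max(baseline, np.finfo(float).tiny) and baseline > 0:
        raise NoAmplificationError("maximum fluorescence below 5x baseline median")
    if amplitude <= 0:
        raise NoAmplificationError("flat curve")
    fs = f
    if smoothing_window and smoothing_window >= 5:
        w = min(smoothing_window | 1, len(f) if len(f) % 2 else len(f) - 1)
        fs = savgol_filter(f, w, polyorder=min(4, w - 1))
    sp = InterpolatedUnivariateSpline(c, fs, k=5)
    grid = np.arange(c[0], c[-1], 0.001)
    vals = sp(grid)
    slope = sp.derivative(1)(grid)
    mid = grid[int(np.argmax(slope))]
    # curvature peaks where the sigmoid has risen ~21% of its amplitude, on
    # the flank left of the maximum slope; restricting the search to that
    # band keeps spline wiggle at the baseline/plateau out of the argmax
    lo, hi = fs.min() + 0.05 * amplitude, fs.min() + 0.60 * amplitude
    band = (grid <= mid) & (vals >= lo) & (vals <= hi)
    if not band.any():
        raise NoAmplificationError("no rising flank found")
    d2 = sp.derivative(2)(grid[band])
    if d2.max() < 0.005 * amplitude:
        raise NoAmplificationError("no curvature consistent with amplification")
    return float(grid[band][int(np.argmax(d2))])


@dataclass
class EfficiencyFit:
    efficiency: float  # amplification factor per cycle (2.0 = perfect doubling)
    slope: float
    r_squared: float
    quality_ok: bool


def efficiency_from_dilution(series: DilutionSeries) -> EfficiencyFit:
    """Amplification efficiency from the Ct-vs-log10(dilution) slope.

    E = 10^(-1/slope); a perfect doubling assay gives slope -3.32 and
    E = 2.  Fits with |slope| < 0.5 or R^2 < 0.9 are flagged as quality
    failures.
    """
    fit = linregress(series.log10_dilution, series.ct)
    slope = float(fit.slope)
    r2 = float(fit.rvalue**2)
    if abs(slope) < 0.5:
        return EfficiencyFit(float("nan"), slope, r2, False)
    e = float(10.0 ** (-1.0 / slope))
    return EfficiencyFit(e, slope, r2, r2 >= 0.9)


def relative_copy_number(
    ct_target: float,
    ct_ref: float,
    ct_target_baseline: float,
    ct_ref_baseline: float,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> float:
    """Efficiency-corrected log2 fold change vs the matched baseline sample.

    fold = (E_target ^ -dCt_target) / (E_ref ^ -dCt_ref) with
    dCt = Ct_sample - Ct_baseline; the reference assay (nuclear 18S rDNA)
    normalizes for template input.
    """
    for name, v in [("ct_target", ct_target), ("ct_ref", ct_ref),
                    ("ct_target_baseline", ct_target_baseline), ("ct_ref_baseline", ct_ref_baseline)]:
        if not np.isfinite(v):
            raise ValueError(f"{name} is not finite")
    d_t = ct_target - ct_target_baseline
    d_r = ct_ref - ct_ref_baseline
    fold = (e_target ** (-d_t)) / (e_ref ** (-d_r))
    return float(np.log2(fold))


def average_technical_replicates(cts) -> tuple[float, float]:
    """Mean and SD of technical-replicate Ct values."""
    v = np.asarray(cts, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite Ct values")
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0
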