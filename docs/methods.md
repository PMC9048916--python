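# Methods

## Measurement model

The pipeline analyzes two-color tiling-microarray measurements of plastid
ribosome footprints and total RNA. One hybridization carries the
acclimating (cold-shifted) sample in channel 635 and its paired control in
channel 532; footprints and RNA are separate hybridizations. The design is
a full factorial over 2 assay layers × 7 post-shift timepoints (0.5 min,
5 min, 20 min, 1 h, 5 h, 1 d, 2 d) × 3 biological replicates, plus a
pre-shift 0-day baseline shared by both conditions (simulated as an array
pair whose two channels both draw from the control process).

Footprint abundance over a reading frame is the proxy for translation
output (each elongating ribosome protects one footprint); translation
efficiency is the footprint/mRNA ratio and separates translational from
transcriptional regulation.

## Normalization cascade

The stage order is fixed and audited by a manifest:

1. **Net signal.** Per probe and channel, F − B (foreground minus local
   background median). Values below a floor of 100 counts are set to
   exactly zero with *background* status; probes whose foreground reaches
   the scanner ceiling (default 65 535, 16-bit) are *saturated* and carry
   no value downstream. The floor is applied to the subtracted value per
   channel.
2. **Global scaling.** Each array's valid coding-probe signals are scaled
   so that every array's mean equals the grand mean of valid coding
   signals pooled over all arrays. A single global scalar would cancel in
   every ratio; per-array centering is what makes hybridizations
   comparable. The pooled grand mean is preserved.
3. **Within-ORF SD normalization.** Per hybridization and reading frame,
   all probe values of both channels are divided by their pooled sample
   SD, equalizing within-ORF variance across replicates (the correction
   for labeling/hybridization efficiency differences). ORFs with pooled
   SD = 0 or fewer than two valid values pass through unscaled and are
   flagged.
4. **Averaging.** Per reading frame and channel, the arithmetic mean over
   valid probes. Background zeros stay in the mean (dropping them would
   bias low-expression genes upward); saturated probes are excluded
   entirely. Entries with fewer than `min_probes = 2` valid probes are
   flagged low-support, not dropped.

## Fold changes and significance

Per replicate, each abundance is normalized to the 0-day baseline of the
same channel, and the acclimating/control contrast is the paired log2
ratio within one hybridization. The reported fold change is the replicate
mean; log2FC_te = log2FC_output − log2FC_rna holds as an identity.

**Why the paired test.** The within-ORF SD factor of stage 3 is shared by
both channels of one hybridization, so it cancels exactly in the paired
per-replicate ratio — but not in an unpaired comparison of the two
baseline-normalized groups, where it appears as common-mode variance. For
reading frames covered by one or two probes that common-mode term is the
dominant variance component and destroys power (empirically p ≈ 0.6–0.99
at a true two-fold change). The default test is therefore the one-sample
Student t of the per-replicate paired log2 ratios against zero (df = n−1);
the unpaired equal-variance two-sample test remains selectable
(`test_mode="two_sample"`). Degenerate convention throughout: zero
variance gives p = 1 at zero mean difference and p = 0 otherwise.

Multiple testing uses Storey q-values with families formed per (measure,
timepoint) across genes. With ~80 genes per family the λ-smoother estimate
of π₀ is unstable, so the default is π₀ = 1 (exactly Benjamini–Hochberg,
conservative); the λ-grid smoother and fixed-λ = 0.5 estimators are
opt-in.

**Classification.** A gene is cold-responsive when |log2FC_output| ≥
log2 1.5 and q < 0.1 at two consecutive or three total post-shift
timepoints ("consecutive" means adjacent in the ordered 7-label series;
the baseline never qualifies). The direction is the sign of the
qualifying fold changes; mixed signs yield *ambiguous*. The gate applies
to the replicate-mean fold change. Empirical top/bottom-decile cutoffs of
the pooled fold changes are reported alongside the fixed 1.5-fold gate.

## Local ribosome redistribution

Relative occupancy r_i = s_i / Σ_ORF s_i is computed per (ORF, layer,
condition, timepoint, replicate); vectors sum to one by construction, so
any local increase forces compensating decreases — redistribution, not
net change. Per-probe acclimating/control log2 ratios are summarized per
timepoint by a parametric Gaussian (μ, σ of the sample; the mass inside
[μ−σ, μ+σ] is evaluated from the normal CDF and equals 68.27%). The
parametric summary is deliberate; a KDE overlay exists for diagnostics
only.

**Probe-level significance.** A per-probe Student t with 2 df cannot
survive FDR correction over ~650 probes (its p-values floor near 1/t²),
so per-probe variances are pooled across the probe family of one (layer,
timepoint) and the mean paired log2 ratio is referred to the normal
distribution (a pooled-variance z test; replicate scatter is well shared
across probes of one array). Replicate pairs where either condition's
occupancy is zero are dropped; probes need at least two informative
pairs. Probes are called redistributed at |log2 ratio| > 1 with q < 0.1
at ≥ 2 consecutive timepoints in the same direction.

## Splicing efficiency

For each adjacent exon pair of an intron-containing reading frame, the
statistic is the paired log2 ratio of (downstream/upstream) exon footprint
abundance, acclimating over control, at the same timepoint; significance
uses the paired t and per-timepoint q-values over all pairs. Genes whose
upstream exon is shorter than 10 nt are excluded (the tobacco-like fixture
ships petB, petD and rpl16 with their characteristic 6–9 nt first exons to
exercise the rule); exon pairs without probes (rps16's 40-nt first exon is
shorter than the 50-nt probes) are reported missing rather than guessed.

## qPCR and polysome computations

Ct is the fractional-cycle location of the second-derivative maximum: the
curve is smoothed with a Savitzky-style local-polynomial filter (window 5
cycles, order 4 — mild by design), interpolated by a quintic spline, and
the spline's second derivative is maximized on a 0.001-cycle grid
restricted to the rising flank between 5% and 60% of the amplitude (the
logistic's curvature peak sits at 21%; the band keeps spline wiggle at
baseline and plateau out of the argmax). Curves must span ≥ 10 cycles,
rise above 5× the baseline median and show curvature ≥ 0.5% of amplitude
per cycle², otherwise a no-amplification error is raised. Amplification
efficiency comes from the least-squares slope of Ct vs log10 dilution
(E = 10^(−1/s); |s| < 0.5 or R² < 0.9 flags a quality failure), and
relative copy number is the efficiency-corrected ratio
(E_t^−ΔCt_t)/(E_r^−ΔCt_r) against the matched baseline, reported in log2.
Technical replicates are averaged at the Ct level. Exact numeric parity
with any instrument's proprietary smoothing is not claimed.

Polysome/monosome ratios are Σ polysome / Σ monosome on sum-normalized
gradient fraction signals; the relative translation-initiation activity is
the acclimating/control ratio of these ratios.

## Synthetic-data generator

A coding probe's expected signal is multiplicative on the log2 scale:

    gene baseline × probe affinity × injected effect(t)
    × 2^(hybridization spot effect) × 2^(channel noise) + additive background

Defaults (chosen once as the shipped study conditions): gene baselines
2^N(11, 1.2²) (median intensity ≈ 3% of the 16-bit ceiling — bright enough
that background censoring is the exception, as the emulated arrays'
replicate reproducibility requires), probe affinity 2^N(0, 0.8²),
hybridization spot effect σ = 0.20 (shared by both channels of one array,
cancelling in within-array ratios as on real two-color arrays),
independent per-channel noise σ = 0.10, background N(60, 15²) counts
drawn separately for the true contamination and the scanner's estimate,
saturation at 65 535. With these components the probe-level replicate
correlation lands near the mid-0.9s, matching the reproducibility regime
the analysis assumes. Probe geometry: 50-nt probes at 100-nt spacing
(configurable; the real array's geometry is not claimed).

Randomness descends from one master seed through per-array substreams
keyed by (layer, timepoint, replicate), so adding arrays never perturbs
existing ones and identical seeds give byte-identical files.

**Effects.** The preset injects (i) 13 cold-responsive output trajectories
(4 up, 9 down; gradual onset, sustained |log2| ≈ 1–2, psbA peaking at
four-fold) with RNA unchanged, so TE mirrors output; (ii) three local
occupancy shifts (+1.5 log2 in atpI and ycf2, −1.8 in psaB), compensated
within the ORF so overall loading is conserved — sites sit in
well-covered, well-expressed frames because a local shift on a 2-probe or
strongly down-regulated gene is unidentifiable after the compensating
rescale or censored by the background floor; (iii) splicing shifts
(ndhA up to +1.1, clpP to −1.0) applied to downstream exons and likewise
compensated, reflecting that splicing changes need not alter whole-ORF
output. Note that a compensated splicing shift also moves the upstream
exon's relative occupancy — redistribution calls in splicing-shifted genes
are expected, not false positives.

**What the generator does not emulate.** Sequence-dependent hybridization
(Tm, cross-hybridization), spatial/print-tip artifacts, dye bias (channel
semantics are fixed, with a dye-swap switch), biological replicate
correlation beyond independent noise, UTR coverage, and trans-splicing
(rps12 is shipped as a cis pair). Passing tests therefore validate the
statistical machinery under the stated noise structure, not robustness to
every artifact of real scans.

## Operating characteristics (computed, not asserted)

`analysis/07_benchmarks.py` and the acceptance suite run the full chain:
null calibration over 50 zero-effect studies (the classifier should be
silent), recovery of the 13 injected genes over 25 seeds (sensitivity and
false-discovery proportion), and redistribution-site recovery over 10
seeds with the conservation check that within-ORF occupancy deltas sum to
zero. Problem sizes — 79 genes, ~690 probes, 48 arrays per study — keep a
single study under a second so the calibrations run in tens of seconds.

## Known limitations

- With 3 replicates the paired t has 2 df; gene-level power for 1-probe
  reading frames sits near the classification boundary, which is why
  single-seed runs occasionally miss one of the weakest injected genes.
- The pooled-variance z test for probes assumes roughly exchangeable
  replicate scatter across probes of a family; strongly heteroscedastic
  probes (near background or saturation) are only partially protected by
  the zero-pair exclusion and the two-fold gate.
- The percentile thresholds describe the realized fold-change
  distribution; on mostly-null synthetic data the deciles sit well inside
  the 1.5-fold gate, unlike on data where a large fraction of genes
  respond.
- Saturation censors the acclimating channel of strongly induced genes
  first, biasing their fold changes slightly toward zero at late
  timepoints.
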