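# plastotrans

Chloroplast gene expression responds to cold not mainly through transcript
levels but through translation: when plants are shifted to low temperature,
the output of individual plastid reading frames changes within minutes to
days while their mRNAs stay nearly constant. `plastotrans` implements the
complete analysis chain for measuring this with microarray-based plastid
ribosome profiling — two-color tiling arrays hybridized with ribosome
footprints and total RNA from paired acclimating/control samples over a
cold-shift time course — together with a synthetic-data generator that
reproduces the statistical structure of such an experiment with known
ground truth, so every stage can be validated end to end without any
external download.

It is written for people analyzing organellar tiling-array translatome
data (or benchmarking methods for it): plant molecular biologists running
cold-shift or similar stress time courses, and method developers who need
a fully specified null and effect model.

## What it computes

For every reading frame *g* and post-shift timepoint *t*, with per-probe
net signals normalized by the fixed cascade (background floor at 100
counts, saturation exclusion, per-array scaling to the grand mean,
within-ORF pooled-SD normalization, averaging):

```
log2FC_output(g,t) = mean_r log2[ (FP_acc(t)/FP_acc(0)) / (FP_con(t)/FP_con(0)) ]
log2FC_rna(g,t)    = the same on the RNA layer
log2FC_te(g,t)     = log2FC_output − log2FC_rna        (translation efficiency)
```

Per-replicate paired log2 ratios are tested with a Student t test against
zero and adjusted per timepoint with Storey q-values (π₀ = 1 by default,
i.e. Benjamini–Hochberg-equivalent). A gene is **cold-responsive** when
|log2FC_output| ≥ log2 1.5 with q < 0.1 at ≥ 2 consecutive or ≥ 3 total
timepoints.

On top of that the package provides:

- **ribosome redistribution (pausing)**: per-probe relative occupancy
  r = s_i / Σ_ORF s, acclimating/control log2 ratios summarized by a
  parametric Gaussian (the band [μ−σ, μ+σ] carries 68.27% of the density),
  and probe calls at a two-fold sustained shift;
- **splicing efficiency**: downstream/upstream exon footprint ratios for
  intron-containing reading frames, excluding genes with 6–9 nt first exons;
- **qPCR copy-number math**: Ct by the second-derivative maximum,
  efficiencies from dilution series (E = 10^(−1/slope)), efficiency-corrected
  log2 fold changes against an 18S rDNA reference;
- **polysome/monosome ratios** from sucrose-gradient fraction signals.

## Worked example

The numbered scripts under `analysis/` run the whole study. Each is a thin
driver over the library; later scripts read the outputs of earlier ones
from `results/`.

```
$ python analysis/01_simulate_study.py --seed 1
simulated 48 arrays over 79 genes (689 probes, 681 in coding regions), seed 1
injected: 13 cold-responsive genes (4 up, 9 down), 3 redistribution sites, 2 splicing shifts

$ python analysis/02_normalize_arrays.py
normalized 48 arrays: 66144 probe-channel entries, 0 saturated (excluded), 870 at background (zeroed)

$ python analysis/03_translation_output.py
called 12 cold-responsive genes (4 up, 8 down) of 79
ground truth: 13 injected; recovered 12, spurious 0
nonessential fraction among responsive: 0.58 (genome-wide 0.22)
psbA peak induction: 4.20-fold

$ python analysis/04_ribosome_redistribution.py
footprint occupancy-ratio density: sigma ranges 0.085-0.161 (widest at 1d); RNA layer stays at 0.088 — redistribution is translational
mass within one sigma of the fitted Gaussian: 68.27%
redistributed probes called: 3 (3 of 3 injected sites recovered)

$ python analysis/05_splicing_efficiency.py
analyzed 8 intron-containing genes (70 exon-pair/timepoint contrasts); excluded: petB, petD, rpl16
  clpP: peak log2 exon-ratio change -1.09 at 1d (injected peak -1.00)
  ndhA: peak log2 exon-ratio change +1.09 at 1d (injected peak +1.10)

$ python analysis/07_benchmarks.py
null calibration: 50/50 zero-effect studies produced zero cold-responsive calls (100% silent)
recovery: sensitivity 0.957, false-discovery proportion 0.000 over 25 seeds
```

Reading the seed-1 run: of 13 injected cold-responsive genes the
classifier recovers 12 with no false calls (the twelfth/thirteenth sit
near the power boundary for 1-probe genes such as petL); the strongest
induction is psbA at ≈ 4-fold; cold-responsive genes are strongly enriched
for nonessential genes relative to the genome (0.58 vs 0.22); the
footprint occupancy-ratio distribution widens after the shift while the
RNA layer stays tight, i.e. ribosomes redistribute along transcripts
without transcript-coverage changes.

The same pipeline runs from a single config through the CLI:

```
plastotrans all --seed 1 --out results/run      # simulate + full analysis
plastotrans all --config run.yaml               # every threshold settable
```

With real scans, point `scans_dir` at a directory of GPR-dialect files
(`Name`, `F635 Median`, `B635 Median`, `F532 Median`, `B532 Median`,
`Flags`; one file per hybridization named `{layer}_{timepoint}_r{rep}.gpr`)
and set `simulate: false`.

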