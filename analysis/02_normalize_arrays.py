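#!/usr/bin/env python
"""Normalize the raw scans into ORF- and exon-level abundances.

Applies the fixed cascade: background subtraction with the 100-count floor
and saturation exclusion, per-array scaling of coding probes to the grand
mean, within-ORF pooled-SD normalization per hybridization, and averaging.
Writes the normalized signal table (probe level), ORF abundances, exon
abundances and the exclusion manifest.
"""

import argparse
import json
from pathlib import Path

from plastotrans.normalize import normalize_scans
from plastotrans.plastome import StudyDesign, assign_probes, read_annotation, read_probe_layout
from plastotrans.simulate import read_gpr


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/01_simulation"))
    ap.add_argument("--out", type=Path, default=Path("results/02_normalized"))
    args = ap.parse_args()

    if not (args.sim / "scans").is_dir():
        raise SystemExit(f"no scans under {args.sim}; run analysis/01_simulate_study.py first")

    design = StudyDesign()
    annotation = read_annotation(args.sim / "annotation.tsv")
    probes = assign_probes(read_probe_layout(args.sim / "probe_layout.tsv"), annotation)

    scans = []
    for layer in design.layers:
        for tp in [design.baseline_label] + design.timepoint_labels:
            for rep in design.replicates:
                scans.append(read_gpr(args.sim / "scans" / f"{layer}_{tp}_r{rep}.gpr", layer, tp, rep))

    abundances, exon_abundances, table, manifest = normalize_scans(scans, probes)

    args.out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    table.assign(coding=table["coding"].astype(int)).to_csv(args.out / "signal_table.tsv", **fmt)
    abundances.to_csv(args.out / "orf_abundances.tsv", **fmt)
    exon_abundances.to_csv(args.out / "exon_abundances.tsv", **fmt)
    with open(args.out / "normalization_manifest.json", "w") as fh:
        json.dump(manifest.as_dict(), fh, indent=2)
        fh.write("\n")

    d = manifest.as_dict()
    print(f"normalized {len(scans)} arrays: {d['n_entries']} probe-channel entries, "
          f"{d['n_saturated']} saturated (excluded), {d['n_background']} at background (zeroed)")
    print(f"{len(abundances)} ORF abundance entries; outputs under {args.out}")


if __name__ == "__main__":
    main()
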