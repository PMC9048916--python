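#!/usr/bin/env python
"""Local ribosome redistribution (pausing) analysis.

Converts probe signals into within-ORF relative occupancies, contrasts
acclimating against control per probe and timepoint, summarizes each
timepoint's log2 ratios with a parametric Gaussian density, and calls
probes whose occupancy shifts more than two-fold with q<0.1 at two
consecutive timepoints.  The RNA layer serves as a negative control.
Optionally draws the per-timepoint probability-density figure.
"""

import argparse
from pathlib import Path

import pandas as pd

from plastotrans.pausing import call_redistributed_probes, density_summaries, occupancy_ratios, relative_occupancy
from plastotrans.plastome import StudyDesign


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/01_simulation"))
    ap.add_argument("--norm", type=Path, default=Path("results/02_normalized"))
    ap.add_argument("--out", type=Path, default=Path("results/04_redistribution"))
    ap.add_argument("--plots", action="store_true", help="write density figures (PNG)")
    args = ap.parse_args()

    design = StudyDesign()
    table = pd.read_csv(args.norm / "signal_table.tsv", sep="\t")
    table["coding"] = table["coding"].astype(bool)

    occ = relative_occupancy(table)
    ratios = occupancy_ratios(occ, design)
    dens_fp = density_summaries(ratios, layer="footprint")
    dens_rna = density_summaries(ratios, layer="rna")
    calls, rollup = call_redistributed_probes(ratios, design)

    args.out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    ratios.to_csv(args.out / "occupancy_ratios.tsv", **fmt)
    dens_fp.assign(layer="footprint").to_csv(args.out / "density_footprint.tsv", **fmt)
    dens_rna.assign(layer="rna").to_csv(args.out / "density_rna.tsv", **fmt)
    pd.DataFrame(
        {"probe_id": [c.probe_id for c in calls], "gene": [c.gene for c in calls],
         "direction": [c.direction for c in calls],
         "timepoints": [",".join(c.timepoints) for c in calls]}
    ).to_csv(args.out / "redistribution_calls.tsv", **fmt)
    rollup.to_csv(args.out / "redistribution_genes.tsv", **fmt)

    truth = pd.read_csv(args.sim / "truth_pausing.tsv", sep="\t")
    sites = set(truth.probe_id)
    called = {c.probe_id for c in calls}
    widest = dens_fp.loc[dens_fp["sigma"].idxmax()]
    print(f"footprint occupancy-ratio density: sigma ranges "
          f"{dens_fp['sigma'].min():.3f}-{dens_fp['sigma'].max():.3f} "
          f"(widest at {widest['timepoint']}); RNA layer stays at "
          f"{dens_rna['sigma'].max():.3f} — redistribution is translational")
    print(f"mass within one sigma of the fitted Gaussian: "
          f"{100 * dens_fp['mass_within_1sd'].iloc[0]:.2f}%")
    print(f"redistributed probes called: {len(calls)} "
          f"({len(called & sites)} of {len(sites)} injected sites recovered)")
    if args.plots:
        _plot(ratios, args.out)
    print(f"outputs under {args.out}")


def _plot(ratios, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np
    from scipy.stats import norm

    for layer, ax_title in (("footprint", "relative ribosome occupancy"),
                            ("rna", "relative transcript coverage")):
        sub = ratios[ratios["layer"] == layer]
        fig, ax = plt.subplots(figsize=(6, 4))
        grid = np.linspace(-1.5, 1.5, 400)
        for tp, g in sub.groupby("timepoint", sort=False):
            v = g["mean_log2_ratio"].dropna()
            ax.plot(grid, norm.pdf(grid, v.mean(), v.std(ddof=1)), label=tp)
        ax.set_xlabel("log2 acclimating/control ratio")
        ax.set_ylabel("probability density")
        ax.set_title(ax_title)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"density_{layer}.png", dpi=150)
        plt.close(fig)


if __name__ == "__main__":
    main()
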