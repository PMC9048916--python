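"""Independent straight-line oracles used by the test suite.

Deliberately unvectorized re-implementations (plain loops, no pandas) of
the normalization cascade and small fixture builders, kept free of any
import from the package modules they check.
"""

import numpy as np
import pandas as pd

from plastotrans.plastome import OrfModel, PlastomeAnnotation
from plastotrans.simulate import ArrayScan


def small_instance(seed: int = 0, n_genes: int = 5, probes_per_gene: int = 8,
                   n_arrays: int = 3):
    """A 5-gene / 40-probe instance with background and saturated probes."""
    rng = np.random.default_rng(seed)
    orfs, layout_rows = [], []
    pos = 0
    for gi in range(n_genes):
        length = probes_per_gene * 60
        orfs.append(OrfModel(f"g{gi}", "+", [(pos, pos + length, 1)], True, "other"))
        for k in range(probes_per_gene):
            layout_rows.append((f"g{gi}p{k}", pos + k * 60, 50))
        pos += length + 200
    annotation = PlastomeAnnotation(orfs, genome_length=pos + 500)
    layout = pd.DataFrame(layout_rows, columns=["probe_id", "start", "length"])

    scans = []
    n_probes = len(layout)
    for a in range(n_arrays):
        f635 = rng.integers(0, 5000, n_probes).astype(float)
        f532 = rng.integers(0, 5000, n_probes).astype(float)
        b = rng.integers(20, 120, n_probes).astype(float)
        # force a few saturated and background entries
        f635[a] = 65535.0
        f532[(a + 5) % n_probes] = 65535.0
        f635[(a + 9) % n_probes] = b[(a + 9) % n_probes] + 30  # below floor
        scans.append(
            ArrayScan(
                "footprint", f"t{a}", 1,
                pd.DataFrame({"probe_id": layout["probe_id"], "f635": f635, "b635": b,
                              "f532": f532, "b532": b, "flags": 0}),
            )
        )
    return annotation, layout, scans


def brute_force_cascade(scans, probe_orf: dict, floor=100.0, saturation=65535.0):
    """Literal loop re-implementation of the normalization cascade.

    Returns {(orf, array_key, condition): abundance} with array_key =
    (layer, timepoint, replicate) and condition the channel semantics
    (635 = acclimating, 532 = control).
    """
    # stage 1: net signals
    net = {}  # (array, probe, channel) -> value or None (saturated)
    for scan in scans:
        akey = (scan.layer, scan.timepoint, scan.replicate)
        for _, row in scan.data.iterrows():
            for ch in ("635", "532"):
                f, b = row[f"f{ch}"], row[f"b{ch}"]
                if f >= saturation:
                    net[(akey, row["probe_id"], ch)] = None
                elif f - b < floor:
                    net[(akey, row["probe_id"], ch)] = 0.0
                else:
                    net[(akey, row["probe_id"], ch)] = f - b
    # stage 2: per-array scaling to the grand mean of valid coding signals
    all_valid = [v for (a, p, c), v in net.items() if v is not None and probe_orf.get(p)]
    grand = sum(all_valid) / len(all_valid)
    arrays = sorted({a for (a, p, c) in net})
    for akey in arrays:
        vals = [v for (a, p, c), v in net.items()
                if a == akey and v is not None and probe_orf.get(p)]
        mean = sum(vals) / len(vals)
        for k in list(net):
            if k[0] == akey and net[k] is not None:
                net[k] = net[k] / mean * grand
    # stage 3: within-ORF pooled-SD normalization per hybridization
    orfs = sorted({o for o in probe_orf.values() if o})
    for akey in arrays:
        for orf in orfs:
            pool = [v for (a, p, c), v in net.items()
                    if a == akey and probe_orf.get(p) == orf and v is not None]
            if len(pool) < 2:
                continue
            mean = sum(pool) / len(pool)
            sd = (sum((x - mean) ** 2 for x in pool) / (len(pool) - 1)) ** 0.5
            if sd == 0:
                continue
            for k in list(net):
                if k[0] == akey and probe_orf.get(k[1]) == orf and net[k] is not None:
                    net[k] = net[k] / sd
    # stage 4: per-ORF, per-channel averaging
    out = {}
    cond = {"635": "acclimating", "532": "control"}
    for akey in arrays:
        for orf in orfs:
            for ch in ("635", "532"):
                vals = [v for (a, p, c), v in net.items()
                        if a == akey and c == ch and probe_orf.get(p) == orf and v is not None]
                if vals:
                    out[(orf, akey, cond[ch])] = sum(vals) / len(vals)
    return out
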