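"""Plastome annotation, probe layout, and study-design models.

Coordinate and naming backbone for the whole pipeline.  All coordinates are
0-based, half-open genomic intervals; conversion to other conventions happens
only at I/O boundaries.  The shipped default annotation is a reduced
tobacco-like plastome: real gene names and plausible lengths laid out on a
synthetic coordinate axis, sufficient to exercise every analysis stage
(intron-containing genes, the short-first-exon trio, essentiality flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPLEX_GROUPS = (
    "PSII",
    "cyt b6f",
    "PSI",
    "NDH",
    "ATP synthase",
    "ribosome SSU",
    "ribosome LSU",
    "RNA polymerase",
    "other",
)


class AnnotationError(ValueError):
    """Raised when an annotation file violates the coordinate model."""


@dataclass
class OrfModel:
    """One plastid reading frame.

    exons are (genomic_start, genomic_end, exon_index) with exon_index
    counting 1..n in transcript (5'->3') orientation; on the minus strand the
    genomic coordinates of successive exons therefore decrease.
    """

    name: str
    strand: str
    exons: list[tuple[int, int, int]]
    essential: bool
    complex_group: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.name}: unknown strand {self.strand!r}")
        if self.complex_group not in COMPLEX_GROUPS:
            raise AnnotationError(
                f"{self.name}: unknown complex group {self.complex_group!r}"
            )
        self.exons = sorted(self.exons, key=lambda e: e[2])
        seen_idx = set()
        for start, end, idx in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"{self.name}: exon {idx} has end <= start ({start}, {end})"
                )
            if idx in seen_idx:
                raise AnnotationError(f"{self.name}: duplicate exon index {idx}")
            seen_idx.add(idx)
        ivs = sorted((s, e) for s, e, _ in self.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.name}: overlapping exons")
        # transcript orientation: exon_index order must follow the strand
        starts = [s for s, _, _ in self.exons]
        if len(starts) > 1:
            ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
            if not ordered:
                raise AnnotationError(
                    f"{self.name}: exon indices not 5'->3' on strand {self.strand}"
                )
        if self.coding_length < 3:
            raise AnnotationError(f"{self.name}: coding length < 3")

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e, _ in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_length(self, exon_index: int) -> int:
        for s, e, i in self.exons:
            if i == exon_index:
                return e - s
        raise KeyError(f"{self.name}: no exon {exon_index}")


@dataclass(frozen=True)
class Probe:
    """A tiling probe; ``orf`` is None for intergenic/ambiguous probes."""

    probe_id: str
    position: int
    length: int
    orf: str | None = None
    exon_index: int | None = None
    ambiguous: bool = False

    @property
    def end(self) -> int:
        return self.position + self.length


#: default post-shift sampling series (label, elapsed seconds)
DEFAULT_TIMEPOINTS: tuple[tuple[str, float], ...] = (
    ("0.5min", 30.0),
    ("5min", 300.0),
    ("20min", 1200.0),
    ("1h", 3600.0),
    ("5h", 18000.0),
    ("1d", 86400.0),
    ("2d", 172800.0),
)


@dataclass
class StudyDesign:
    """Factorial layout of the cold-shift time course.

    Paired acclimating/control samples are hybridized on one array per
    (layer, timepoint, replicate); the pre-shift baseline sample is shared by
    both conditions and labelled ``baseline_label``.
    """

    timepoints: tuple[tuple[str, float], ...] = DEFAULT_TIMEPOINTS
    baseline_label: str = "0d"
    conditions: tuple[str, str] = ("acclimating", "control")
    n_replicates: int = 3
    layers: tuple[str, ...] = ("footprint", "rna")

    def __post_init__(self) -> None:
        secs = [s for _, s in self.timepoints]
        if any(b <= a for a, b in zip(secs, secs[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (t-tests need >= 2)")
        if self.baseline_label in self.timepoint_labels:
            raise ValueError("baseline label collides with a post-shift timepoint")

    @property
    def timepoint_labels(self) -> list[str]:
        return [lbl for lbl, _ in self.timepoints]

    @property
    def replicates(self) -> list[int]:
        return list(range(1, self.n_replicates + 1))


class PlastomeAnnotation:
    """Ordered collection of :class:`OrfModel` keyed by gene name."""

    def __init__(self, orfs: list[OrfModel], genome_length: int | None = None):
        self.orfs: dict[str, OrfModel] = {}
        for orf in orfs:
            if orf.name in self.orfs:
                raise AnnotationError(f"duplicate ORF {orf.name}")
            self.orfs[orf.name] = orf
        if genome_length is None:
            genome_length = max((e for o in orfs for _, e, _ in o.exons), default=0) + 1000
        self.genome_length = genome_length

    def __getitem__(self, name: str) -> OrfModel:
        return self.orfs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.orfs

    def __iter__(self):
        return iter(self.orfs.values())

    def __len__(self) -> int:
        return len(self.orfs)

    @property
    def gene_names(self) -> list[str]:
        return list(self.orfs)

    def intron_containing(self) -> list[OrfModel]:
        return [o for o in self if o.n_exons > 1]

    def essential_split(self, genes: list[str] | None = None) -> tuple[int, int]:
        """(n_essential, n_nonessential) over ``genes`` (default: all)."""
        names = self.gene_names if genes is None else genes
        ess = sum(1 for g in names if self[g].essential)
        return ess, len(names) - ess


# ---------------------------------------------------------------------------
# I/O: BED-like annotation TSV and probe layout TSV
# ---------------------------------------------------------------------------

_ANN_COLS = ["chrom", "start", "end", "name", "exon_index", "strand", "essential", "complex_group"]


def read_annotation(path) -> PlastomeAnnotation:
    """Read a BED-like TSV (one row per exon) into a validated annotation.

    Columns: chrom, start, end, name, exon_index, strand, essential
    ('essential'/'nonessential'), complex_group.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_ANN_COLS):
                raise AnnotationError(f"line {lineno}: expected {len(_ANN_COLS)} columns")
            chrom, start, end, name, exon_index, strand, essential, group = parts
            if strand not in ("+", "-"):
                raise AnnotationError(f"line {lineno}: unknown strand symbol {strand!r}")
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise AnnotationError(f"line {lineno}: exon end <= start for {name}")
            if essential not in ("essential", "nonessential"):
                raise AnnotationError(f"line {lineno}: essential flag {essential!r}")
            rows.append((name, start_i, end_i, int(exon_index), strand, essential == "essential", group))
    by_gene: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for name, s, e, idx, strand, ess, group in rows:
        by_gene.setdefault(name, []).append((s, e, idx))
        if name in meta and meta[name] != (strand, ess, group):
            raise AnnotationError(f"{name}: inconsistent strand/flags across exon rows")
        meta[name] = (strand, ess, group)
    orfs = [
        OrfModel(name=g, strand=meta[g][0], exons=ex, essential=meta[g][1], complex_group=meta[g][2])
        for g, ex in by_gene.items()
    ]
    return PlastomeAnnotation(orfs)


def write_annotation(annotation: PlastomeAnnotation, path, chrom: str = "plastome") -> None:
    """Write the canonical BED-like TSV (exon rows in transcript order)."""
    with open(path, "w") as fh:
        for orf in annotation:
            flag = "essential" if orf.essential else "nonessential"
            for s, e, idx in orf.exons:
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{orf.name}\t{idx}\t{orf.strand}\t{flag}\t{orf.complex_group}\n"
                )


def read_probe_layout(path) -> pd.DataFrame:
    """Probe layout TSV with columns probe_id, start, length."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    missing = {"probe_id", "start", "length"} - set(df.columns)
    if missing:
        raise ValueError(f"probe layout missing columns: {sorted(missing)}")
    return df


def write_probe_layout(layout: pd.DataFrame, path) -> None:
    layout[["probe_id", "start", "length"]].to_csv(path, sep="\t", index=False)


def assign_probes(layout: pd.DataFrame, annotation: PlastomeAnnotation) -> list[Probe]:
    """Map each probe to at most one (ORF, exon).

    A probe counts toward an ORF only if it lies entirely within a single
    exon of that ORF.  Probes overlapping coding sequence without full
    containment (exon-boundary or two-gene spanners) are flagged ambiguous;
    probes touching no exon are intergenic.  Deterministic and independent
    of row order.
    """
    if layout["probe_id"].duplicated().any():
        dup = layout.loc[layout["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r} in layout")
    ex_start, ex_end, ex_orf, ex_idx = [], [], [], []
    for orf in annotation:
        for s, e, idx in orf.exons:
            ex_start.append(s)
            ex_end.append(e)
            ex_orf.append(orf.name)
            ex_idx.append(idx)
    ex_start = np.asarray(ex_start)
    ex_end = np.asarray(ex_end)

    p_start = layout["start"].to_numpy()
    p_end = p_start + layout["length"].to_numpy()
    # containment / overlap masks, probes x exons
    overlaps = (p_start[:, None] < ex_end[None, :]) & (p_end[:, None] > ex_start[None, :])
    contained = (p_start[:, None] >= ex_start[None, :]) & (p_end[:, None] <= ex_end[None, :])

    probes: list[Probe] = []
    for i, row in enumerate(layout.itertuples(index=False)):
        hit = np.flatnonzero(contained[i])
        if len(hit) == 1:
            j = int(hit[0])
            probes.append(
                Probe(row.probe_id, int(row.start), int(row.length), ex_orf[j], int(ex_idx[j]))
            )
        elif overlaps[i].any():
            probes.append(Probe(row.probe_id, int(row.start), int(row.length), ambiguous=True))
        else:
            probes.append(Probe(row.probe_id, int(row.start), int(row.length)))
    return probes


def probe_frame(probes: list[Probe]) -> pd.DataFrame:
    """Tabular view of assigned probes (one row per probe)."""
    return pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "start": [p.position for p in probes],
            "length": [p.length for p in probes],
            "orf": [p.orf for p in probes],
            "exon_index": [p.exon_index for p in probes],
            "ambiguous": [p.ambiguous for p in probes],
        }
    )


# ---------------------------------------------------------------------------
# Default reduced tobacco-like plastome fixture
# ---------------------------------------------------------------------------

# (name, exon lengths 5'->3', essential, complex group).  Lengths are
# plausible tobacco values; multi-exon entries are the intron-containing
# reading frames.  petB/petD/rpl16 carry their characteristic 6-9 nt first
# exons, which the splicing analysis must refuse to quantify.
_DEFAULT_GENES: list[tuple[str, list[int], bool, str]] = [
    ("psbA", [1062], True, "PSII"),
    ("psbB", [1527], True, "PSII"),
    ("psbC", [1386], True, "PSII"),
    ("psbD", [1062], True, "PSII"),
    ("psbE", [252], True, "PSII"),
    ("psbF", [120], True, "PSII"),
    ("psbH", [222], True, "PSII"),
    ("psbI", [111], True, "PSII"),
    ("psbJ", [123], True, "PSII"),
    ("psbK", [186], True, "PSII"),
    ("psbL", [117], True, "PSII"),
    ("psbM", [105], False, "PSII"),
    ("psbN", [132], True, "PSII"),
    ("psbT", [108], True, "PSII"),
    ("psbZ", [189], False, "PSII"),
    ("psaA", [2253], True, "PSI"),
    ("psaB", [2205], True, "PSI"),
    ("psaC", [246], True, "PSI"),
    ("psaI", [111], False, "PSI"),
    ("psaJ", [135], False, "PSI"),
    ("petA", [963], True, "cyt b6f"),
    ("petB", [6, 642], True, "cyt b6f"),
    ("petD", [8, 475], True, "cyt b6f"),
    ("petG", [114], True, "cyt b6f"),
    ("petL", [96], False, "cyt b6f"),
    ("petN", [90], True, "cyt b6f"),
    ("atpA", [1524], True, "ATP synthase"),
    ("atpB", [1497], True, "ATP synthase"),
    ("atpE", [402], True, "ATP synthase"),
    ("atpF", [145, 410], True, "ATP synthase"),
    ("atpH", [246], True, "ATP synthase"),
    ("atpI", [744], True, "ATP synthase"),
    ("ndhA", [553, 539], False, "NDH"),
    ("ndhB", [777, 756], False, "NDH"),
    ("ndhC", [363], False, "NDH"),
    ("ndhD", [1503], False, "NDH"),
    ("ndhE", [306], False, "NDH"),
    ("ndhF", [2223], False, "NDH"),
    ("ndhG", [531], False, "NDH"),
    ("ndhH", [1182], False, "NDH"),
    ("ndhI", [504], False, "NDH"),
    ("ndhJ", [477], False, "NDH"),
    ("ndhK", [678], False, "NDH"),
    ("rbcL", [1434], True, "other"),
    ("matK", [1530], True, "other"),
    ("cemA", [690], True, "other"),
    ("ccsA", [966], True, "other"),
    ("accD", [1467], True, "other"),
    ("clpP", [71, 292, 228], True, "other"),
    ("ycf1", [5391], True, "other"),
    ("ycf2", [6837], True, "other"),
    ("ycf3", [124, 230, 153], True, "other"),
    ("ycf4", [555], True, "other"),
    ("infA", [234], True, "other"),
    ("rpoA", [1014], True, "RNA polymerase"),
    ("rpoB", [3213], True, "RNA polymerase"),
    ("rpoC1", [432, 1638], True, "RNA polymerase"),
    ("rpoC2", [4176], True, "RNA polymerase"),
    ("rps2", [711], True, "ribosome SSU"),
    ("rps3", [657], True, "ribosome SSU"),
    ("rps4", [606], True, "ribosome SSU"),
    ("rps7", [468], True, "ribosome SSU"),
    ("rps8", [405], True, "ribosome SSU"),
    ("rps11", [417], True, "ribosome SSU"),
    ("rps12", [114, 232], True, "ribosome SSU"),
    ("rps14", [303], True, "ribosome SSU"),
    ("rps15", [273], False, "ribosome SSU"),
    ("rps16", [40, 227], True, "ribosome SSU"),
    ("rps18", [306], True, "ribosome SSU"),
    ("rps19", [279], True, "ribosome SSU"),
    ("rpl2", [391, 434], True, "ribosome LSU"),
    ("rpl14", [369], True, "ribosome LSU"),
    ("rpl16", [9, 399], True, "ribosome LSU"),
    ("rpl20", [387], True, "ribosome LSU"),
    ("rpl22", [398], True, "ribosome LSU"),
    ("rpl23", [282], True, "ribosome LSU"),
    ("rpl32", [174], True, "ribosome LSU"),
    ("rpl33", [201], True, "ribosome LSU"),
    ("rpl36", [114], True, "ribosome LSU"),
]

INTRON_LENGTH = 600  # synthetic spacer between exons of one reading frame
GENE_SPACER = 200


def default_annotation() -> PlastomeAnnotation:
    """Reduced tobacco-like plastome laid out on a synthetic axis.

    Genes follow each other with fixed intergenic spacers; every fourth gene
    is placed on the minus strand so both orientations are exercised.
    """
    orfs = []
    pos = 1000
    for k, (name, exon_lens, essential, group) in enumerate(_DEFAULT_GENES):
        strand = "-" if k % 4 == 3 else "+"
        exons = []
        if strand == "+":
            p = pos
            for i, ln in enumerate(exon_lens, start=1):
                exons.append((p, p + ln, i))
                p += ln + INTRON_LENGTH
            span_end = exons[-1][1]
        else:
            # exon 1 is genomically last so transcript runs 5'->3' downstream
            span = sum(exon_lens) + INTRON_LENGTH * (len(exon_lens) - 1)
            p = pos + span
            for i, ln in enumerate(exon_lens, start=1):
                exons.append((p - ln, p, i))
                p -= ln + INTRON_LENGTH
            span_end = pos + span
        orfs.append(OrfModel(name, strand, exons, essential, group))
        pos = span_end + GENE_SPACER
    return PlastomeAnnotation(orfs, genome_length=pos + 1000)


def default_probe_layout(
    annotation: PlastomeAnnotation,
    probe_length: int = 50,
    spacing: int = 100,
    intergenic_every: int = 10,
) -> pd.DataFrame:
    """Tile every exon with fixed-length probes at fixed spacing.

    Exons shorter than ``probe_length`` receive no probe.  One intergenic
    probe is dropped into every ``intergenic_every``-th gene spacer as a
    negative control.  probe_ids encode the genomic start, so the layout is
    fully determined by the annotation and the two geometry parameters.
    """
    rows = []
    for orf in annotation:
        for s, e, _idx in sorted(orf.exons, key=lambda x: x[0]):
            p = s
            while p + probe_length <= e:
                rows.append((f"pr{p:07d}", p, probe_length))
                p += spacing
    spacer_starts = []
    bounds = sorted((min(s for s, _, _ in o.exons), max(e for _, e, _ in o.exons)) for o in annotation)
    for k, ((_, e1), (s2, _)) in enumerate(zip(bounds, bounds[1:])):
        if k % intergenic_every == 0 and s2 - e1 >= probe_length + 20:
            p = e1 + 10
            spacer_starts.append((f"pr{p:07d}", p, probe_length))
    rows.extend(spacer_starts)
    df = pd.DataFrame(rows, columns=["probe_id", "start", "length"])
    return df.sort_values("start", ignore_index=True)
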