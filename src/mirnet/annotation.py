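"""ChIP peak-to-gene assignment via strand-aware binding windows.

A binding peak is linked to a locus when the peak midpoint falls inside the
locus's regulatory window: for protein-coding genes the window runs from
2000 bp upstream to 300 bp downstream of the TSS; for miRNA loci it covers
the 2000 bp upstream of the first base of the annotated pre-miRNA.

Coordinates are 0-based half-open internally (BED native); GFF3 input
(1-based inclusive) is converted on read.  Windows are closed intervals,
inclusive on both ends, and the midpoint of an even-length peak is the lower
median, floor((start + end) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: context labels in default priority order (highest first)
DEFAULT_CONTEXT_PRIORITY = ("five_prime_utr", "three_prime_utr", "exon", "intron", "intergenic")

_GFF_STRUCTURE_TYPES = {
    "exon": "exon",
    "five_prime_UTR": "five_prime_utr",
    "three_prime_UTR": "three_prime_utr",
}


@dataclass(frozen=True)
class Peak:
    """A ChIP binding peak interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    tf_id: str
    score: float | None = None
    peak_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.peak_id or ''}: start must be < end "
                             f"({self.start} >= {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneAnchor:
    """Strand-aware regulatory anchor of a locus.

    ``anchor`` is the TSS for coding genes and the first base of the
    pre-miRNA for miRNA loci (0-based).  ``span`` is the gene body and
    ``structure`` an optional list of ``(label, start, end)`` intervals
    (labels: exon, five_prime_utr, three_prime_utr) used for genomic-context
    classification.
    """

    gene_id: str
    chrom: str
    strand: str
    anchor: int
    gene_class: str
    span: tuple[int, int] | None = None
    structure: tuple[tuple[str, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.gene_class not in ("coding", "mirna"):
            raise ValueError(f"{self.gene_id}: gene_class must be coding or mirna")
        if self.anchor < 0:
            raise ValueError(f"{self.gene_id}: negative anchor coordinate")


@dataclass(frozen=True)
class WindowParams:
    """Binding-window extents in bp (defaults follow the TSS -2000/+300 and
    pre-miRNA -2000/0 conventions)."""

    coding_upstream: int = 2000
    coding_downstream: int = 300
    mirna_upstream: int = 2000
    mirna_downstream: int = 0

    def __post_init__(self) -> None:
        for name in ("coding_upstream", "coding_downstream",
                     "mirna_upstream", "mirna_downstream"):
            if getattr(self, name) < 0:
                raise ValueError(f"window parameter {name} must be nonnegative")


def compute_window(anchor: GeneAnchor, params: WindowParams = WindowParams()) -> tuple[int, int]:
    """Closed genomic interval [lo, hi] of the binding window of ``anchor``.

    Upstream/downstream are oriented by strand and the window is clipped at
    coordinate 0.
    """
    if anchor.gene_class == "coding":
        up, down = params.coding_upstream, params.coding_downstream
    else:
        up, down = params.mirna_upstream, params.mirna_downstream
    if anchor.strand == "+":
        lo, hi = anchor.anchor - up, anchor.anchor + down
    else:
        lo, hi = anchor.anchor - down, anchor.anchor + up
    return (max(lo, 0), max(hi, 0))


@dataclass
class PeakAssignments:
    """Result of :func:`assign_peaks_to_genes`.

    ``assignments`` is peak-level (one row per peak x containing window);
    ``edges`` is deduplicated to unique (tf_id, gene_id) pairs with the
    supporting peak count, ready for edge construction.
    """

    assignments: pd.DataFrame
    edges: pd.DataFrame
    unmatched_chroms: set[str] = field(default_factory=set)


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    anchors: Sequence[GeneAnchor],
    params: WindowParams = WindowParams(),
) -> PeakAssignments:
    """Assign each peak to every locus whose window contains its midpoint.

    A peak may hit several overlapping windows; associations are also rolled
    up to unique (tf_id, gene_id) pairs.  Peaks on chromosomes absent from
    the anchor set are recorded in ``unmatched_chroms``.
    """
    trees: dict[str, IntervalTree] = {}
    anchor_by_id = {}
    for a in anchors:
        lo, hi = compute_window(a, params)
        trees.setdefault(a.chrom, IntervalTree())
        # closed [lo, hi] -> half-open [lo, hi + 1)
        trees[a.chrom].addi(lo, hi + 1, a.gene_id)
        anchor_by_id[a.gene_id] = a

    rows = []
    unmatched = set()
    for i, p in enumerate(peaks):
        tree = trees.get(p.chrom)
        if tree is None:
            unmatched.add(p.chrom)
            continue
        pid = p.peak_id or f"peak{i:06d}"
        for hit in tree.at(p.midpoint):
            rows.append((pid, p.tf_id, hit.data, p.chrom, p.midpoint,
                         anchor_by_id[hit.data].gene_class))
    assignments = pd.DataFrame(
        rows, columns=["peak_id", "tf_id", "gene_id", "chrom", "midpoint", "gene_class"]
    ).sort_values(["tf_id", "gene_id", "peak_id"], ignore_index=True)

    if len(assignments):
        edges = (assignments.groupby(["tf_id", "gene_id", "gene_class"], as_index=False)
                 .size().rename(columns={"size": "n_peaks"}))
    else:
        edges = pd.DataFrame(columns=["tf_id", "gene_id", "gene_class", "n_peaks"])
    return PeakAssignments(assignments=assignments, edges=edges, unmatched_chroms=unmatched)


def assignments_to_edge_tables(result: PeakAssignments) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rolled-up associations into TMI and TTI edge tables.

    Associations to miRNA loci become TMI candidate edges, those to coding
    genes TTI candidates; both tables are directly consumable by network
    assembly.
    """
    def _table(sub: pd.DataFrame, cls: str) -> pd.DataFrame:
        return pd.DataFrame({
            "source": sub["tf_id"].astype(str),
            "target": sub["gene_id"].astype(str),
            "edge_class": cls,
            "sign": "unknown",
            "evidence": ["peaks:" + str(n) for n in sub["n_peaks"]],
        })

    edges = result.edges
    tmi = _table(edges[edges["gene_class"] == "mirna"], "TMI")
    tti = _table(edges[edges["gene_class"] == "coding"], "TTI")
    return tmi.reset_index(drop=True), tti.reset_index(drop=True)


def classify_peak_context(
    peak: Peak,
    anchors: Sequence[GeneAnchor],
    priority: Sequence[str] = DEFAULT_CONTEXT_PRIORITY,
) -> str:
    """Genomic context of the peak midpoint: UTRs, exon, intron or intergenic.

    When the midpoint falls into overlapping features (of one gene or of
    several), the label earliest in ``priority`` wins; anything outside all
    gene bodies is intergenic.
    """
    mid = peak.midpoint
    found: set[str] = set()
    for a in anchors:
        if a.chrom != peak.chrom or a.span is None:
            continue
        lo, hi = a.span
        if not (lo <= mid < hi):
            continue
        inner = {label for label, s, e in a.structure or () if s <= mid < e}
        found.add(min(inner, key=priority.index) if inner else "intron")
    if not found:
        return "intergenic"
    return min(found, key=priority.index)


def metagene_profile(
    peaks: Sequence[Peak],
    anchors: Sequence[GeneAnchor],
    window: tuple[int, int] = (-2000, 500),
    bin_size: int = 50,
) -> pd.DataFrame:
    """Histogram of peak midpoints by strand-oriented offset from anchors.

    Offsets are negative upstream of the anchor and positive downstream on
    either strand.  Returns a DataFrame with ``offset`` (bin left edge) and
    ``count``; counts sum to the number of in-window (peak, anchor) pairs.
    """
    if not anchors:
        raise ValueError("metagene profile requires at least one anchor")
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be a nonempty (lo, hi) range")
    if (hi - lo) % bin_size != 0:
        raise ValueError("bin size must divide the window length")
    edges = np.arange(lo, hi + bin_size, bin_size)
    offsets = []
    by_chrom: dict[str, list[GeneAnchor]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    for p in peaks:
        mid = p.midpoint
        for a in by_chrom.get(p.chrom, ()):
            off = mid - a.anchor if a.strand == "+" else a.anchor - mid
            if lo <= off < hi:
                offsets.append(off)
    counts, _ = np.histogram(offsets, bins=edges)
    return pd.DataFrame({"offset": edges[:-1], "count": counts})


# ---------------------------------------------------------------------------
# I/O: BED6 peaks and GFF3 anchors
# ---------------------------------------------------------------------------

def read_peaks_bed(path: str | Path) -> list[Peak]:
    """Read peaks from BED (>= 4 columns); the name column carries the TF id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: need BED with at least 4 columns (name = TF id)")
    peaks = []
    for i, row in df.iterrows():
        score = None
        if df.shape[1] >= 5 and row[4] not in (".", "", None):
            score = float(row[4])
        peaks.append(Peak(chrom=row[0], start=int(row[1]), end=int(row[2]),
                          tf_id=row[3], score=score, peak_id=f"peak{i:06d}"))
    return peaks


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf_id}\t{score}\t+\n")
    return path


def read_anchors_gff3(path: str | Path) -> list[GeneAnchor]:
    """Parse gene and pre-miRNA anchors (plus exon/UTR structure) from GFF3.

    Coding genes come from ``gene`` features (anchor = TSS), miRNA loci from
    ``miRNA_primary_transcript`` features (anchor = first transcribed base).
    Exon and UTR children are attached via their ``Parent`` attribute.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    anchors: list[GeneAnchor] = []
    for ftype, gene_class in (("gene", "coding"), ("miRNA_primary_transcript", "mirna")):
        for feat in db.features_of_type(ftype):
            start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
            anchor = start0 if feat.strand == "+" else end0 - 1
            structure = []
            for child in db.children(feat.id):
                label = _GFF_STRUCTURE_TYPES.get(child.featuretype)
                if label:
                    structure.append((label, child.start - 1, child.end))
            structure.sort(key=lambda t: (t[1], t[2], t[0]))
            anchors.append(GeneAnchor(
                gene_id=feat.id, chrom=feat.seqid, strand=feat.strand, anchor=anchor,
                gene_class=gene_class, span=(start0, end0),
                structure=tuple(structure) or None,
            ))
    anchors.sort(key=lambda a: (a.chrom, a.anchor, a.gene_id))
    return anchors


def write_anchors_gff3(anchors: Sequence[GeneAnchor], path: str | Path) -> Path:
    """Write anchors (and any structure intervals) as GFF3."""
    inverse_types = {v: k for k, v in _GFF_STRUCTURE_TYPES.items()}
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for a in sorted(anchors, key=lambda a: (a.chrom, a.span or (a.anchor, a.anchor), a.gene_id)):
            span = a.span or (a.anchor, a.anchor + 1)
            ftype = "gene" if a.gene_class == "coding" else "miRNA_primary_transcript"
            fh.write(f"{a.chrom}\tmirnetsim\t{ftype}\t{span[0] + 1}\t{span[1]}\t.\t"
                     f"{a.strand}\t.\tID={a.gene_id}\n")
            for k, (label, s, e) in enumerate(a.structure or ()):
                fh.write(f"{a.chrom}\tmirnetsim\t{inverse_types[label]}\t{s + 1}\t{e}\t.\t"
                         f"{a.strand}\t.\tID={a.gene_id}.{label}.{k};Parent={a.gene_id}\n")
    return path
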