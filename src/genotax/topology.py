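"""Replicon classification and circular-topology validation from long reads.

Two independent evidence streams are combined per contig:

* marker-gene content — core housekeeping genes and rRNA operon components
  (dnaA, gyrA/gyrB, rpoB, recA, 16S/23S rRNA, parA/parB) identify
  chromosomal sequence, conjugation / type IV secretion genes (virB family,
  tra genes, repABC) identify putative plasmids;
* long-read alignment geometry — mean coverage, the fraction of secondary
  alignments (a repeat signal), junction-spanning reads (alignments within
  a fixed window, 5 kb by default, of both contig termini: direct evidence
  of circularity), and coverage-doubled blocks indicating a collapsed
  near-identical duplication.

A contig is called circular only when enough distinct reads span the
junction and no coverage-doubled block touches a terminus window — a
collapsed repeat at the junction makes apparent spanning reads untrustworthy
and leaves the true topology unresolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .simulate import AlignmentRecord

logger = logging.getLogger(__name__)

DEFAULT_JUNCTION_WINDOW = 5_000
DEFAULT_MIN_JUNCTION_READS = 3
DEFAULT_CHROM_MARKER_MIN = 4
DEFAULT_COVERAGE_WINDOW = 5_000
DEFAULT_DOUBLING_FACTOR = 1.6

CHROMOSOME = "chromosome"
CHROMOSOMAL_FRAGMENT = "chromosomal_fragment"
PUTATIVE_PLASMID = "putative_plasmid"
UNCLASSIFIED = "unclassified"


def load_marker_vocabulary() -> dict[str, str]:
    """Controlled marker vocabulary shipped with the package:
    gene symbol (lower-case) -> {chromosome, plasmid}."""
    vocab: dict[str, str] = {}
    text = (resources.files("genotax.data") / "replicon_markers.tsv"
            ).read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, category = line.split("\t")
        vocab[gene.strip().lower()] = category.strip()
    return vocab


@dataclass
class AnnotationSet:
    contig_id: str
    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = {g.lower() for g in self.genes}


@dataclass
class TopologyEvidence:
    contig_id: str
    mean_coverage: float
    secondary_fraction: float
    junction_reads: int
    coverage_doubled_blocks: list[tuple[int, int, float]] = field(
        default_factory=list)
    verdict: str = "linear_or_unresolved"   # or "circular"


def classify_replicon(annotation: AnnotationSet,
                      chrom_marker_min: int = DEFAULT_CHROM_MARKER_MIN,
                      vocabulary: dict[str, str] | None = None) -> str:
    """Marker-content rule.

    chromosome            >= chrom_marker_min distinct chromosomal markers
    chromosomal_fragment  1 .. chrom_marker_min-1 chromosomal markers
                          (separate fragments of an unresolved chromosome)
    putative_plasmid      >= 1 plasmid marker, below the chromosomal set
    unclassified          no recognized markers

    Plasmid markers on a contig carrying a full chromosomal marker set do
    not override the chromosome call. Unknown symbols are ignored with a
    logged warning.
    """
    vocab = vocabulary if vocabulary is not None else load_marker_vocabulary()
    chrom = plasmid = 0
    for gene in sorted(annotation.genes):
        cat = vocab.get(gene)
        if cat == "chromosome":
            chrom += 1
        elif cat == "plasmid":
            plasmid += 1
        else:
            logger.warning("unknown marker gene %r on contig %s ignored",
                           gene, annotation.contig_id)
    if chrom >= chrom_marker_min:
        return CHROMOSOME
    if chrom >= 1:
        return CHROMOSOMAL_FRAGMENT
    if plasmid >= 1:
        return PUTATIVE_PLASMID
    return UNCLASSIFIED


def mean_coverage(alignments: list[AlignmentRecord],
                  contig_length: int) -> float:
    """Primary-alignment bases divided by contig length (fold coverage)."""
    if contig_length <= 0:
        raise ValueError(f"contig_length must be positive, got "
                         f"{contig_length}")
    total = sum(a.span for a in alignments if not a.is_secondary)
    return total / contig_length


def secondary_fraction(alignments: list[AlignmentRecord]) -> float:
    """Fraction of alignment records flagged secondary; NaN on no input."""
    if not alignments:
        return float("nan")
    return sum(a.is_secondary for a in alignments) / len(alignments)


def junction_spanning_reads(alignments: list[AlignmentRecord],
                            contig_length: int,
                            window: int = DEFAULT_JUNCTION_WINDOW) -> int:
    """Distinct reads with an alignment starting within `window` of the
    contig start AND one ending within `window` of the contig end (possibly
    the same record). Reads are counted by read_id, so a wrap split into two
    records counts once; secondary placements are excluded."""
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if contig_length <= 2 * window:
        raise ValueError(
            f"contig ({contig_length} bp) too short for a {window} bp "
            f"junction window")
    near_start: set[str] = set()
    near_end: set[str] = set()
    for a in alignments:
        if a.is_secondary:
            continue
        if a.start < window:
            near_start.add(a.read_id)
        if a.end > contig_length - window:
            near_end.add(a.read_id)
    return len(near_start & near_end)


def detect_coverage_doubling(alignments: list[AlignmentRecord],
                             contig_length: int,
                             window: int = DEFAULT_COVERAGE_WINDOW,
                             doubling_factor: float = DEFAULT_DOUBLING_FACTOR,
                             min_windows: int = 3,
                             extend_factor: float = 1.35
                             ) -> list[tuple[int, int, float]]:
    """Maximal runs of windows whose primary-read depth is at least
    `doubling_factor` times the contig's baseline window depth, merged into
    intervals (start, end, mean_fold). The signature of a collapsed
    near-identical duplication: both true copies' reads pile onto one locus.

    Runs shorter than `min_windows` are discarded and gaps of up to
    `min_windows` below-threshold windows inside a run are closed over:
    collapsed duplications of interest span tens of kilobases, while
    single elevated (or briefly dipping) windows are routine sampling
    noise at long-read lengths.
    """
    if contig_length <= window:
        return []
    n_win = contig_length // window
    edges = np.arange(n_win + 1) * window
    depth = np.zeros(n_win)
    for a in alignments:
        if a.is_secondary:
            continue
        lo, hi = a.start, min(a.end, int(edges[-1]))
        if hi <= lo:
            continue
        first, last = lo // window, (hi - 1) // window
        for w in range(first, min(last, n_win - 1) + 1):
            overlap = min(hi, edges[w + 1]) - max(lo, edges[w])
            depth[w] += overlap
    depth /= window
    # Baseline = 30th percentile of window depths: robust to the doubled
    # block itself inflating the centre when it occupies a large share of
    # a desk-scale contig (a whole-chromosome average would be untouched).
    baseline = float(np.percentile(depth, 30))
    if baseline == 0:
        return []
    # Seed-and-extend with hysteresis: a block needs at least one window
    # at doubling_factor x baseline, but extends through contiguous
    # windows above a lower bound, so local sampling dips do not split a
    # genuine collapsed region.
    core = depth >= doubling_factor * baseline
    extend = depth >= extend_factor * baseline
    flagged = np.zeros(n_win, dtype=bool)
    w = 0
    while w < n_win:
        if extend[w]:
            start = w
            while w < n_win and extend[w]:
                w += 1
            if core[start:w].any():
                flagged[start:w] = True
        else:
            w += 1
    # close short gaps between flagged runs
    w = 0
    while w < n_win:
        if not flagged[w]:
            gap_start = w
            while w < n_win and not flagged[w]:
                w += 1
            if (gap_start > 0 and w < n_win
                    and w - gap_start <= min_windows):
                flagged[gap_start:w] = True
        else:
            w += 1
    blocks: list[tuple[int, int, float]] = []
    w = 0
    while w < n_win:
        if flagged[w]:
            start = w
            while w < n_win and flagged[w]:
                w += 1
            if w - start >= min_windows:
                fold = float(np.mean(depth[start:w]) / baseline)
                blocks.append((int(edges[start]), int(edges[w]), fold))
        else:
            w += 1
    return blocks


def assess_topology(contig_id: str,
                    alignments: list[AlignmentRecord],
                    contig_length: int,
                    window: int = DEFAULT_JUNCTION_WINDOW,
                    min_junction_reads: int = DEFAULT_MIN_JUNCTION_READS,
                    coverage_window: int = DEFAULT_COVERAGE_WINDOW,
                    doubling_factor: float = DEFAULT_DOUBLING_FACTOR
                    ) -> TopologyEvidence:
    """Combine the per-contig read evidence into a topology verdict.

    circular  iff  junction_reads >= min_junction_reads and no coverage-
    doubled block overlaps a terminus window; otherwise
    linear_or_unresolved, with all evidence attached either way.

    For contigs too short to hold two full junction windows (small
    plasmids), the window shrinks to a quarter of the contig.
    """
    if not alignments:
        return TopologyEvidence(contig_id, 0.0, float("nan"), 0, [],
                                "linear_or_unresolved")
    if contig_length <= 2 * window:
        window = max(1, contig_length // 4)
    cov = mean_coverage(alignments, contig_length)
    sec = secondary_fraction(alignments)
    junctions = junction_spanning_reads(alignments, contig_length, window)
    blocks = detect_coverage_doubling(alignments, contig_length,
                                      coverage_window, doubling_factor)
    # only a substantial collapsed block can fake junction-spanning reads;
    # short noise blocks must not veto an otherwise clean circular call
    min_block = 4 * coverage_window
    terminus_hit = any(
        (e - s) >= min_block
        and (s < window or e > contig_length - window)
        for s, e, _ in blocks)
    verdict = ("circular"
               if junctions >= min_junction_reads and not terminus_hit
               else "linear_or_unresolved")
    return TopologyEvidence(contig_id, cov, sec, junctions, blocks, verdict)
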