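"""Synthetic genome, read and clade simulators.

Every downstream stage of the pipeline (fragment ANI, topology validation,
core-SNP phylogeny, threshold classification) is exercised on genomes built
here, so the generators reproduce the statistical structure the analysis
assumes rather than realistic sequence content:

* multi-replicon genomes with a high-GC chromosome (~63%) and lower-GC
  plasmids (~61%), the hallmark of *Bradyrhizobium* assemblies;
* controlled pairwise divergence: a uniform (Jukes–Cantor-like) per-site
  substitution process whose rate maps directly onto target ANI values;
* unique-sequence insertions that decouple alignment fraction from ANI;
* large near-identical repeats that create secondary alignments and, when
  collapsed, twofold coverage blocks and unresolved junctions;
* long reads sampled uniformly from circular and linear replicons, with
  origin-wrapping reads split into two alignment records the way a real
  mapper reports them;
* clonal phylogenies with planted recombinant (high-SNP-density) imports.

Reads carry no base-level error model: alignment records carry truth
placements, because no downstream stage here consumes base errors.
All randomness flows through a single integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .errors import FormatError
from .genome import Genome, Replicon, ints_to_seq, seq_to_ints


# ---------------------------------------------------------------------------
# ancestral sequence and per-site divergence
# ---------------------------------------------------------------------------

def generate_ancestor(
    length: int, gc: float, seed: int, replicon_id: str = "anc",
    circular: bool = False, role: str = "chromosome",
) -> Replicon:
    """Draw an i.i.d. random sequence of `length` bp with expected GC `gc`.

    Bases are sampled independently with P(G) = P(C) = gc/2 and
    P(A) = P(T) = (1-gc)/2, so the realized GC fraction is binomial
    around `gc` with sd sqrt(gc(1-gc)/length).
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be a fraction in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return Replicon(id=replicon_id, seq=ints_to_seq(codes),
                    circular=circular, role_truth=role)


MAX_SUB_RATE = 0.75  # above 3/4 a uniform substitution model is meaningless


def _mutate_codes(codes: np.ndarray, sub_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with prob sub_rate, uniformly to a
    different base (add 1..3 mod 4 in code space)."""
    hit = rng.random(codes.shape[0]) < sub_rate
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out = codes.copy()
    out[hit] = (out[hit] + shift) % 4
    return out


def mutate(replicon: Replicon, sub_rate: float, seed: int) -> Replicon:
    """Return a copy with independent per-site substitutions at `sub_rate`.

    Length is preserved; the expected Hamming distance is sub_rate × length.
    """
    if not 0.0 <= sub_rate < MAX_SUB_RATE:
        raise ValueError(
            f"sub_rate must be in [0, {MAX_SUB_RATE}), got {sub_rate}")
    if sub_rate == 0.0:
        return Replicon(replicon.id, replicon.seq, replicon.circular,
                        replicon.role_truth)
    rng = np.random.default_rng(seed)
    codes = _mutate_codes(seq_to_ints(replicon.seq), sub_rate, rng)
    return Replicon(replicon.id, ints_to_seq(codes), replicon.circular,
                    replicon.role_truth)


def insert_unique(replicon: Replicon, fraction: float, seed: int,
                  block_length: int = 2000) -> Replicon:
    """Insert freshly generated unique sequence totalling fraction×length.

    Inserted material is split into blocks of ~`block_length` bp placed at
    random positions; the original bases are left untouched, so fragment ANI
    is preserved while the alignment fraction drops to ≈ 1/(1+fraction).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0:
        return Replicon(replicon.id, replicon.seq, replicon.circular,
                        replicon.role_truth)
    rng = np.random.default_rng(seed)
    total = int(round(fraction * len(replicon)))
    n_blocks = max(1, int(round(total / block_length)))
    sizes = np.full(n_blocks, total // n_blocks)
    sizes[: total - sizes.sum()] += 1
    gc = replicon.gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    positions = np.sort(rng.integers(0, len(replicon) + 1, size=n_blocks))
    parts: list[str] = []
    prev = 0
    for pos, size in zip(positions, sizes):
        parts.append(replicon.seq[prev:pos])
        block = rng.choice(4, size=int(size), p=p).astype(np.uint8)
        parts.append(ints_to_seq(block))
        prev = pos
    parts.append(replicon.seq[prev:])
    return Replicon(replicon.id, "".join(parts), replicon.circular,
                    replicon.role_truth)


@dataclass
class RepeatTruth:
    """Planted repeat family: intervals of each copy on the output replicon."""

    copies: list[tuple[int, int]]
    identity: float


def _rate_for_pairwise_identity(identity: float) -> float:
    """Per-copy substitution rate e so that two copies independently mutated
    from a master at rate e have expected pairwise identity `identity`.

    P(same) = (1-e)^2 + e^2/3  =>  (4/3)e^2 - 2e + (1 - identity) = 0.
    """
    if identity >= 1.0:
        return 0.0
    disc = 4.0 - (16.0 / 3.0) * (1.0 - identity)
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def plant_repeat(replicon: Replicon, repeat_len: int, copies: int,
                 identity: float, seed: int) -> tuple[Replicon, RepeatTruth]:
    """Overwrite `copies` random non-overlapping loci with near-identical
    copies of one repeat at expected mutual identity `identity`.

    Emulates the large (~80–90 kb) homologous chromosomal segments that
    defeat long-read circularization. Returns the modified replicon and the
    truth coordinates of each copy.
    """
    if copies < 2:
        raise ValueError(f"copies must be >= 2, got {copies}")
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    if repeat_len * copies >= len(replicon):
        raise ValueError(
            f"{copies} copies of {repeat_len} bp do not fit in "
            f"{len(replicon)} bp")
    rng = np.random.default_rng(seed)
    # Rejection-sample non-overlapping starts.
    starts: list[int] = []
    for _ in range(10_000):
        cand = int(rng.integers(0, len(replicon) - repeat_len + 1))
        if all(abs(cand - s) >= repeat_len for s in starts):
            starts.append(cand)
            if len(starts) == copies:
                break
    else:
        raise ValueError("could not place non-overlapping repeat copies")
    starts.sort()
    master = generate_ancestor(repeat_len, replicon.gc,
                               int(rng.integers(0, 2**31)))
    master_codes = seq_to_ints(master.seq)
    rate = _rate_for_pairwise_identity(identity)
    seq = np.frombuffer(replicon.seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for s in starts:
        copy_codes = _mutate_codes(master_codes, rate, rng)
        seq[s: s + repeat_len] = lut[copy_codes]
    out = Replicon(replicon.id, seq.tobytes().decode("ascii"),
                   replicon.circular, replicon.role_truth)
    truth = RepeatTruth(copies=[(s, s + repeat_len) for s in starts],
                        identity=identity)
    return out, truth


# ---------------------------------------------------------------------------
# long-read simulation with truth alignment records
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    read_id: str
    source_replicon: str
    start: int          # 0-based offset of the read's first base
    length: int
    wraps_origin: bool
    seq: str


@dataclass
class AlignmentRecord:
    """One placement of a read on a contig, 0-based half-open."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    is_secondary: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


MIN_REPEAT_OVERLAP = 200   # ~seedable overlap before a secondary is emitted


def _draw_lengths(n: int, mean: int, rng: np.random.Generator,
                  min_length: int) -> np.ndarray:
    """Gamma(shape=3) read lengths around `mean`, floored at min_length."""
    lens = rng.gamma(shape=3.0, scale=mean / 3.0, size=n)
    return np.maximum(lens.astype(np.int64), max(min_length, 50))


def simulate_reads(
    genome: Genome,
    mean_depth: float,
    length_mean: int,
    seed: int,
    min_length: int = 0,
    repeats: dict[str, list[RepeatTruth]] | None = None,
    collapsed_repeats: dict[str, list[tuple[int, int, float]]] | None = None,
) -> tuple[list[SimulatedRead], list[AlignmentRecord]]:
    """Sample long reads uniformly over each replicon and emit truth placements.

    Circular replicons draw start positions over the whole length, so reads
    may wrap the origin; a wrapping read is emitted as two primary alignment
    records (the terminal part and the leading part), as a mapper would
    report it. Linear replicons never wrap.

    `repeats` (per-replicon planted repeat families) drive secondary-record
    emission: a read falling inside one copy of a family with identity >= 0.9
    gets one secondary record at the homologous offset of each other copy.

    `collapsed_repeats` maps replicon id -> [(start, end, extra_fold)]:
    additional reads are sampled from those intervals to emulate a collapsed
    duplication whose two true copies both map onto one assembled locus.
    """
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be positive, got {mean_depth}")
    if length_mean <= 0:
        raise ValueError(f"length_mean must be positive, got {length_mean}")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    records: list[AlignmentRecord] = []
    counter = 0
    repeats = repeats or {}
    collapsed_repeats = collapsed_repeats or {}

    for rep in genome.replicons:
        L = len(rep)
        n_reads = max(1, int(round(mean_depth * L / length_mean)))
        lengths = np.minimum(_draw_lengths(n_reads, length_mean, rng,
                                           min_length), L)
        if rep.circular:
            starts = rng.integers(0, L, size=n_reads)
        else:
            starts = np.array([int(rng.integers(0, L - l + 1))
                               for l in lengths])
        fams = [f for f in repeats.get(rep.id, []) if f.identity >= 0.9]

        for start, length in zip(starts.tolist(), lengths.tolist()):
            counter += 1
            rid = f"{genome.strain_id}_{rep.id}_r{counter}"
            wraps = rep.circular and start + length > L
            if wraps:
                seq = rep.seq[start:] + rep.seq[: start + length - L]
                reads.append(SimulatedRead(rid, rep.id, start, length, True,
                                           seq))
                records.append(AlignmentRecord(rid, rep.id, start, L))
                records.append(AlignmentRecord(rid, rep.id, 0,
                                               start + length - L))
            else:
                seq = rep.seq[start: start + length]
                reads.append(SimulatedRead(rid, rep.id, start, length, False,
                                           seq))
                records.append(AlignmentRecord(rid, rep.id, start,
                                               start + length))
                # a read overlapping one repeat copy maps secondarily to
                # the homologous stretch of each other copy
                for fam in fams:
                    for ci, (cs, ce) in enumerate(fam.copies):
                        ov0 = max(start, cs)
                        ov1 = min(start + length, ce)
                        if ov1 - ov0 < MIN_REPEAT_OVERLAP:
                            continue
                        off0, off1 = ov0 - cs, ov1 - cs
                        for cj, (os_, _oe) in enumerate(fam.copies):
                            if cj == ci:
                                continue
                            records.append(AlignmentRecord(
                                rid, rep.id, os_ + off0, os_ + off1,
                                is_secondary=True))
                        break

        # reads from the second (collapsed-away) copy map onto the single
        # assembled copy, clipped sharply at the repeat boundaries
        for (cs, ce, extra_fold) in collapsed_repeats.get(rep.id, []):
            span = ce - cs
            n_extra = max(0, int(round(
                extra_fold * mean_depth * (span + length_mean)
                / length_mean)))
            ex_lens = _draw_lengths(n_extra, length_mean, rng, min_length)
            for l in ex_lens.tolist():
                s = int(rng.integers(cs - l, ce))
                a0, a1 = max(s, cs), min(s + l, ce)
                if a1 - a0 < MIN_REPEAT_OVERLAP:
                    continue
                counter += 1
                rid = f"{genome.strain_id}_{rep.id}_x{counter}"
                reads.append(SimulatedRead(rid, rep.id, a0, a1 - a0, False,
                                           rep.seq[a0:a1]))
                records.append(AlignmentRecord(rid, rep.id, a0, a1))

    return reads, records


# ---------------------------------------------------------------------------
# clonal clade simulation with planted recombinant imports
# ---------------------------------------------------------------------------

@dataclass
class CladeSim:
    """Specification of a clonal clade: a rooted tree with branch lengths, a
    per-site per-branch-unit substitution rate, and optional imported
    segments (taxon, start, end, donor_divergence) laid over the clonal
    frame."""

    tree_truth: str | TreeNode
    substitution_rate: float
    recomb_segments: list[tuple[str, int, int, float]] = field(
        default_factory=list)
    gc: float = 0.63

    def tree(self) -> TreeNode:
        if isinstance(self.tree_truth, TreeNode):
            return self.tree_truth
        try:
            return TreeNode.read([self.tree_truth])
        except Exception as exc:  # skbio raises several parse error types
            raise FormatError(f"malformed newick tree: {exc}") from exc

    def __post_init__(self) -> None:
        per_taxon: dict[str, list[tuple[int, int]]] = {}
        for taxon, start, end, div in self.recomb_segments:
            if end <= start:
                raise ValueError(f"empty recomb segment {start}-{end}")
            if div <= 0:
                raise ValueError("donor_divergence must be positive")
            for s, e in per_taxon.get(taxon, []):
                if start < e and s < end:
                    raise ValueError(
                        f"overlapping recomb segments for taxon {taxon!r}")
            per_taxon.setdefault(taxon, []).append((start, end))


@dataclass
class CladeTruth:
    tree: TreeNode
    recomb_mask: dict[str, list[tuple[int, int]]]
    variable_sites: np.ndarray  # positions polymorphic among the leaves


def simulate_clade(sim: CladeSim, genome_length: int, seed: int
                   ) -> tuple[dict[str, Genome], CladeTruth]:
    """Evolve one chromosome along the truth tree and overlay imports.

    Substitution is site-independent and uniform: along a branch of length b
    each site substitutes with probability min(rate*b, 0.74), uniformly to a
    different base. Imported segments are then re-substituted at their donor
    divergence, producing the dense SNP clusters the recombination masker is
    built to find.
    """
    tree = sim.tree()
    tips = [t.name for t in tree.tips()]
    if len(tips) < 3:
        raise FormatError(f"tree must have >= 3 taxa, got {len(tips)}")
    if any(t is None for t in tips):
        raise FormatError("tree has unnamed tips")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise FormatError("negative branch length in tree")

    rng = np.random.default_rng(seed)
    root = generate_ancestor(genome_length, sim.gc, int(rng.integers(0, 2**31)))
    root_codes = seq_to_ints(root.seq)

    leaf_codes: dict[str, np.ndarray] = {}

    def _evolve(node, codes: np.ndarray) -> None:
        for child in node.children:
            b = child.length or 0.0
            p = min(sim.substitution_rate * b, 0.74)
            child_codes = _mutate_codes(codes, p, rng) if p > 0 else codes
            if child.is_tip():
                leaf_codes[child.name] = child_codes.copy()
            else:
                _evolve(child, child_codes)

    _evolve(tree, root_codes)

    # Segments sharing (start, end, donor_divergence) are imports of the
    # same donor haplotype (one divergent lineage recombining into several
    # recipients) — receiving taxa become locally identical, the situation
    # that actually distorts clonal-frame phylogenies.
    mask: dict[str, list[tuple[int, int]]] = {}
    donors: dict[tuple[int, int, float], np.ndarray] = {}
    for taxon, start, end, div in sim.recomb_segments:
        if taxon not in leaf_codes:
            raise ValueError(f"recomb segment names unknown taxon {taxon!r}")
        key = (start, end, div)
        if key not in donors:
            donors[key] = _mutate_codes(root_codes[start:end], div, rng)
        leaf_codes[taxon][start:end] = donors[key]
        mask.setdefault(taxon, []).append((start, end))

    stacked = np.stack([leaf_codes[t] for t in tips])
    variable = np.where((stacked != stacked[0]).any(axis=0))[0]

    genomes = {
        t: Genome(strain_id=t,
                  replicons=[Replicon(id="chr", seq=ints_to_seq(c),
                                      circular=False,
                                      role_truth="chromosome")])
        for t, c in leaf_codes.items()
    }
    return genomes, CladeTruth(tree=tree, recomb_mask=mask,
                               variable_sites=variable)
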