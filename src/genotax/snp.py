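"""Core-SNP matrix construction, missing-data filtering, iterative
recombination masking, and distance-based phylogeny.

Assemblies (not reads) are the input: each query genome is aligned against
a reference replicon through the same fragment machinery used for ANI, and
substitutions inside reciprocal fragment matches become variants at
reference coordinates. Core SNPs are positions covered in every strain that
are polymorphic among the strains.

Recombination masking follows the Gubbins idea at desk scale: imported
segments betray themselves as windows whose taxon-specific SNP density far
exceeds that taxon's genome-wide (clonal) density. Flagged windows are
masked to missing, and the scan repeats until no new windows appear or an
iteration cap is reached; a tree is rebuilt each round. Tree inference is
neighbor-joining on pairwise SNP distances normalized by shared non-missing
sites — the alignment exports (FASTA/TSV) let users run likelihood tools
externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from . import ani
from .genome import Genome, Replicon, revcomp

MISSING = "N"
DEFAULT_MAX_MISSING = 0.31
DEFAULT_RECOMB_WINDOW = 1_000
DEFAULT_DENSITY_FACTOR = 5.0
DEFAULT_MAX_ITER = 5
MIN_WINDOW_SNPS = 8      # absolute floor so sparse clonal windows never flag
MAX_DISTANCE = 0.75      # distance assigned to pairs with no shared sites


@dataclass
class VariantSet:
    """Substitutions of one strain relative to the reference, plus the set
    of reference positions its assembly actually covered."""

    strain_id: str
    variants: dict[int, str]
    covered: np.ndarray          # bool per reference position
    ref_length: int

    def __post_init__(self) -> None:
        if self.covered.shape[0] != self.ref_length:
            raise ValueError("covered mask length != ref_length")
        for pos in self.variants:
            if not self.covered[pos]:
                raise ValueError(
                    f"variant at uncovered position {pos} "
                    f"(strain {self.strain_id})")

    @property
    def missing_fraction(self) -> float:
        return 1.0 - float(self.covered.mean())


def call_variants(reference: Replicon, query: Genome,
                  fragment_length: int = ani.DEFAULT_FRAGMENT_LENGTH
                  ) -> VariantSet:
    """Call substitutions of `query` against `reference` via reciprocal
    fragment matches; gap columns are not emitted as variants (the fragment
    model is substitution-oriented) but still consume coordinates."""
    ref_genome = Genome(strain_id="__ref__",
                        replicons=[Replicon(reference.id, reference.seq,
                                            reference.circular,
                                            "chromosome")])
    iq = ani.GenomeIndex(query, fragment_length=fragment_length)
    ir = ani.GenomeIndex(ref_genome, fragment_length=fragment_length)
    covered = np.zeros(len(reference), dtype=bool)
    variants: dict[int, str] = {}
    if not iq.fragments() or not ir.fragments():
        return VariantSet(query.strain_id, {}, covered, len(reference))
    mqr = ani._direction_matches(iq, ir, ani.MATCH_FLOOR, ani.COVERAGE_FLOOR)
    mrq = ani._direction_matches(ir, iq, ani.MATCH_FLOOR, ani.COVERAGE_FLOOR)
    pairs = ani._reciprocal_pairs(mqr, mrq, iq, ir)
    frags = iq.fragments()
    pad = 60
    for qi, _ in pairs:
        m = mqr[qi]
        ts, te = m.target_span
        qseq = frags[qi][1]
        if m.strand == "-":
            qseq = revcomp(qseq)
        # realign semi-globally on a padded window so terminal mismatches
        # trimmed during match scoring are still walked as variants
        w0 = max(0, ts - pad)
        w1 = min(len(reference), te + pad)
        res = edlib.align(qseq, reference.seq[w0:w1], mode="HW",
                          task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        loc = min(res["locations"])
        ts = w0 + loc[0]
        te2 = w0 + loc[1] + 1
        covered[ts:te2] = True
        # Prefer a gapless columnwise reading when it explains the span
        # almost as well as the edit-optimal alignment: edit-optimal paths
        # re-express neighboring substitutions as balanced gaps, which
        # would shift or drop substitution calls.
        gapless = _best_gapless(qseq, reference.seq, ts, te2)
        if gapless is not None:
            anchor, mism = gapless
            if len(mism) <= res["editDistance"] + 4:
                covered[anchor: anchor + len(qseq)] = True
                for o in mism:
                    variants[anchor + o] = qseq[o]
                continue
        q = t = 0
        for op_len, op in _canonical_ops(res["cigar"]):
            if op == "=":
                q += op_len
                t += op_len
            elif op == "X":
                for o in range(op_len):
                    if qseq[q + o] != reference.seq[ts + t + o]:
                        variants[ts + t + o] = qseq[q + o]
                q += op_len
                t += op_len
            elif op == "I":
                q += op_len
            elif op == "D":
                t += op_len
    return VariantSet(query.strain_id, variants, covered, len(reference))


def _best_gapless(qseq: str, ref: str, ts: int, te: int
                  ) -> tuple[int, list[int]] | None:
    """Best gapless placement of qseq anchored at either end of the matched
    reference span: (reference start, mismatch offsets), or None if the
    query does not fit."""
    best = None
    for anchor in {ts, te - len(qseq)}:
        if anchor < 0 or anchor + len(qseq) > len(ref):
            continue
        mism = [o for o, (qb, rb) in enumerate(
            zip(qseq, ref[anchor: anchor + len(qseq)])) if qb != rb]
        if best is None or len(mism) < len(best[1]):
            best = (anchor, mism)
    return best


def _canonical_ops(cigar: str):
    """CIGAR runs with equal-cost adjacent insertion/deletion pairs
    re-expressed as mismatch columns (edlib may encode two neighboring
    substitutions as I+D; for variant calling the substitution reading is
    canonical). Converted X columns are re-checked against the reference
    base before a variant is emitted."""
    ops = list(_cigar_ops(cigar))
    i = 0
    while i < len(ops):
        if i + 1 < len(ops) and {ops[i][1], ops[i + 1][1]} == {"I", "D"}:
            n1, o1 = ops[i]
            n2, o2 = ops[i + 1]
            sub = min(n1, n2)
            if n1 > sub:
                yield n1 - sub, o1
            yield sub, "X"
            if n2 > sub:
                yield n2 - sub, o2
            i += 2
        else:
            yield ops[i]
            i += 1


def reference_variant_set(reference: Replicon, strain_id: str) -> VariantSet:
    """The reference itself as a taxon: fully covered, zero variants.
    Useful when the reference strain should appear in the tree."""
    return VariantSet(strain_id, {},
                      np.ones(len(reference), dtype=bool), len(reference))


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


# ---------------------------------------------------------------------------
# core SNP matrix
# ---------------------------------------------------------------------------

@dataclass
class SNPMatrix:
    positions: np.ndarray           # strictly increasing reference positions
    taxa: list[str]
    states: np.ndarray              # (n_taxa, n_positions) of single chars
    ref_states: np.ndarray          # reference base per column
    missing_fraction: dict[str, float]
    ref_length: int

    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])

    def copy(self) -> "SNPMatrix":
        return SNPMatrix(self.positions.copy(), list(self.taxa),
                         self.states.copy(), self.ref_states.copy(),
                         dict(self.missing_fraction), self.ref_length)

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{''.join(row)}\n"
                       for t, row in zip(self.taxa, self.states))

    def to_tsv(self) -> str:
        lines = ["position\t" + "\t".join(self.taxa)]
        for c in range(self.n_sites):
            lines.append(str(int(self.positions[c])) + "\t"
                         + "\t".join(self.states[:, c]))
        return "\n".join(lines) + "\n"


def build_matrix(variant_sets: list[VariantSet],
                 reference: Replicon) -> SNPMatrix:
    """Core polymorphic sites: reference positions covered in ALL strains
    where at least two distinct states occur among the strains. Per-taxon
    missing fractions are recorded from coverage before the core
    restriction."""
    if len(variant_sets) < 2:
        raise ValueError("need at least 2 strains to build a SNP matrix")
    names = [v.strain_id for v in variant_sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strain ids")
    core = np.ones(len(reference), dtype=bool)
    for v in variant_sets:
        if v.ref_length != len(reference):
            raise ValueError("variant set reference length mismatch")
        core &= v.covered
    candidates = sorted({p for v in variant_sets for p in v.variants
                         if core[p]})
    positions, columns = [], []
    ref_arr = reference.seq
    for pos in candidates:
        ref_base = ref_arr[pos]
        col = [v.variants.get(pos, ref_base) for v in variant_sets]
        if len(set(col)) >= 2:
            positions.append(pos)
            columns.append(col)
    states = (np.array(columns, dtype="<U1").T if columns
              else np.empty((len(variant_sets), 0), dtype="<U1"))
    return SNPMatrix(
        positions=np.array(positions, dtype=np.int64),
        taxa=names, states=states,
        ref_states=np.array([ref_arr[p] for p in positions], dtype="<U1"),
        missing_fraction={v.strain_id: v.missing_fraction
                          for v in variant_sets},
        ref_length=len(reference))


def _drop_uninformative(matrix: SNPMatrix) -> SNPMatrix:
    """Remove columns without >= 2 distinct non-missing states."""
    keep = []
    for c in range(matrix.n_sites):
        col = matrix.states[:, c]
        if len({s for s in col if s != MISSING}) >= 2:
            keep.append(c)
    keep_arr = np.array(keep, dtype=np.int64)
    return SNPMatrix(matrix.positions[keep_arr], list(matrix.taxa),
                     matrix.states[:, keep_arr], matrix.ref_states[keep_arr],
                     dict(matrix.missing_fraction), matrix.ref_length)


def filter_missing(matrix: SNPMatrix, max_missing: float = DEFAULT_MAX_MISSING
                   ) -> tuple[SNPMatrix, list[str]]:
    """Drop taxa whose missing-data fraction (uncovered reference fraction)
    exceeds `max_missing`, then drop columns made uninformative."""
    if not 0.0 < max_missing <= 1.0:
        raise ValueError(f"max_missing must be in (0, 1], got {max_missing}")
    excluded = [t for t in matrix.taxa
                if matrix.missing_fraction[t] > max_missing]
    if not excluded:
        return matrix.copy(), []
    keep = [i for i, t in enumerate(matrix.taxa) if t not in excluded]
    out = SNPMatrix(matrix.positions.copy(),
                    [matrix.taxa[i] for i in keep],
                    matrix.states[keep, :].copy(),
                    matrix.ref_states.copy(),
                    {t: matrix.missing_fraction[t]
                     for i, t in enumerate(matrix.taxa) if i in set(keep)},
                    matrix.ref_length)
    return _drop_uninformative(out), excluded


# ---------------------------------------------------------------------------
# recombination masking
# ---------------------------------------------------------------------------

@dataclass
class RecombMask:
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    iterations_run: int = 0

    def merged(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for taxon, ivs in self.intervals.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[taxon] = [(s, e) for s, e in merged]
        return out

    def to_bed(self) -> str:
        lines = [f"{t}\t{s}\t{e}" for t, ivs in sorted(self.merged().items())
                 for s, e in ivs]
        return "\n".join(lines) + ("\n" if lines else "")


def mask_recombination(matrix: SNPMatrix,
                       window: int = DEFAULT_RECOMB_WINDOW,
                       density_factor: float = DEFAULT_DENSITY_FACTOR,
                       max_iter: int = DEFAULT_MAX_ITER
                       ) -> tuple[RecombMask, SNPMatrix]:
    """Iteratively mask per-taxon windows of elevated SNP density.

    Per iteration a tree is rebuilt, then for each taxon the reference is
    scanned in fixed windows; a window is flagged when that taxon's SNP
    count in it reaches density_factor x its genome-wide SNP density x
    window (with an absolute floor of MIN_WINDOW_SNPS). Flagged sites are
    set to missing for that taxon. Convergence: an iteration that flags
    nothing new. The mask only ever grows.
    """
    work = matrix.copy()
    mask = RecombMask()
    if max_iter <= 0 or work.n_sites == 0:
        return mask, work
    already: set[tuple[str, int]] = set()
    for iteration in range(1, max_iter + 1):
        mask.iterations_run = iteration
        if len(work.taxa) >= 3 and work.n_sites > 0:
            build_tree(work)   # per-iteration rebuild, Gubbins-style
        new_flags: list[tuple[str, int]] = []
        for ti, taxon in enumerate(work.taxa):
            row = work.states[ti]
            snp_cols = np.where((row != MISSING) & (row != work.ref_states)
                                )[0]
            n_snps = snp_cols.size
            if n_snps == 0:
                continue
            genome_density = n_snps / work.ref_length
            threshold = max(density_factor * genome_density * window,
                            MIN_WINDOW_SNPS)
            wins = work.positions[snp_cols] // window
            counts = np.bincount(wins)
            for w in np.where(counts >= threshold)[0]:
                key = (taxon, int(w))
                if key not in already:
                    new_flags.append(key)
        if not new_flags:
            break
        for taxon, w in new_flags:
            already.add((taxon, w))
            ti = work.taxa.index(taxon)
            lo, hi = w * window, (w + 1) * window
            cols = np.where((work.positions >= lo) & (work.positions < hi)
                            )[0]
            work.states[ti, cols] = MISSING
            mask.intervals.setdefault(taxon, []).append((lo, hi))
    mask.intervals = mask.merged()
    return mask, _drop_uninformative(work)


# ---------------------------------------------------------------------------
# neighbor-joining tree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    newick: str
    tree: TreeNode
    degenerate: bool = False


def snp_distance_matrix(matrix: SNPMatrix) -> DistanceMatrix:
    """Pairwise SNP differences normalized by shared non-missing sites;
    taxa ordered lexicographically for deterministic downstream joins."""
    order = sorted(range(len(matrix.taxa)), key=lambda i: matrix.taxa[i])
    taxa = [matrix.taxa[i] for i in order]
    n = len(taxa)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ra = matrix.states[order[a]]
            rb = matrix.states[order[b]]
            shared = (ra != MISSING) & (rb != MISSING)
            ns = int(shared.sum())
            dist = (float((ra[shared] != rb[shared]).sum()) / ns
                    if ns else MAX_DISTANCE)
            d[a, b] = d[b, a] = dist
    return DistanceMatrix(d, taxa)


def build_tree(matrix: SNPMatrix) -> PhyloTree:
    """Neighbor-joining tree from the SNP distance matrix.

    A matrix with zero columns yields a star tree flagged degenerate
    rather than an error, so pipelines can continue and report it.
    """
    if len(matrix.taxa) < 3:
        raise ValueError("need at least 3 taxa to build a tree")
    if matrix.n_sites == 0:
        taxa = sorted(matrix.taxa)
        newick = "(" + ",".join(f"{t}:0" for t in taxa) + ");"
        return PhyloTree(newick, TreeNode.read([newick]), degenerate=True)
    dm = snp_distance_matrix(matrix)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    newick = str(tree).strip()
    return PhyloTree(newick, tree, degenerate=False)
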