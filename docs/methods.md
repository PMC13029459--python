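# Methods

This note documents the models, algorithms, parameter choices and known
limitations of genotax, in the spirit of a package manual rather than a
results report. Every number quoted as a behavior is recomputed by the test
suite or by `scripts/acceptance.py`; nothing here is an empirical claim
beyond what those runs measure.

## Fragment ANI, AF and the dDDH-like distance

Both genomes are concatenated per strain (replicons joined with `N`
spacers; fragments never cross replicon boundaries) and cut into
consecutive, non-overlapping windows of `fragment_length` (default
1020 bp, the convention of fragment-based ANI tools; trailing remainders
are discarded). Each fragment is placed on the partner genome by k-mer
seeding (k = 15, query k-mers sampled every 6 bp, diagonal voting in
128 bp bins, up to 4 candidate diagonals per strand, seeds occurring more
than 50 times skipped as repeat-saturated) followed by exact semi-global
edit-distance alignment (edlib, bit-parallel Myers DP) of the fragment
against the candidate window. The alignment is scored on its best local
block (match +1, mismatch −1, gap base −2, Kadane over CIGAR runs): a
fragment straddling a unique-sequence insertion is thereby scored on its
homologous part only, which is what keeps ANI near 100% while AF drops.
Identity = matches / block columns. Fragments whose best identity falls
below 0.35, or whose aligned query coverage falls below 0.35, are
unmatched — the standard noise floor preventing unrelated sequence from
dragging ANI downward. Ties in identity break toward the lowest target
coordinate, then the forward strand, making results order-independent.

A fragment pair (i, j) is **reciprocal** when i's best-hit midpoint falls
in fragment j and vice versa. Then

* ANI = 100 × mean over reciprocal pairs of the two directional block
  identities (symmetric by construction);
* AF = 100 × n_reciprocal / max(n_fragments_A, n_fragments_B). The
  denominator is the larger fragment count: self-comparison gives exactly
  100, and padding either genome with unique sequence reduces AF toward
  1/(1+f) symmetrically. (Defining AF against the query side alone would
  report ~100% for the un-padded genome and break the symmetry users
  expect of a matrix.)
* dDDH-like = 100 × Σ(block matches) / Σ(block columns) over both
  directions of the reciprocal pairs. This is the identities/HSP-length
  summary ratio printed alongside digital-hybridization output; it is
  explicitly *not* a reimplementation of the GGDC distance formulas or
  their logistic-regression probability, which are out of scope.

When no reciprocal pair exists (unrelated genomes) the result is flagged
undefined with ANI = NaN, never a silent zero.

Numerical behavior verified in the suite: self-ANI exactly 100/100;
ANI within ±0.3 points of the per-site substitution truth at rates
0.005–0.05 on 200 kb pairs; agreement within 0.5 points with a single
whole-genome exact DP alignment on small genomes; strict monotonicity in
divergence; |ANI(A,B) − ANI(B,A)| ≤ 0.5.

## Replicon classification and topology validation

Marker vocabulary (shipped as `data/replicon_markers.tsv`): chromosomal —
dnaA, gyrA, gyrB, rpoB, recA, 16S/23S rRNA, parA, parB; plasmid —
virB2/4/9/11, virD4, traG, traI, trbA, repA/B/C. A contig is a
*chromosome* with ≥ 4 distinct chromosomal markers (`chrom_marker_min`,
configurable — "complete marker set" is not a published count), a
*chromosomal_fragment* with 1–3, a *putative_plasmid* with ≥ 1 plasmid
marker and fewer than 4 chromosomal markers, else *unclassified*. Plasmid
markers never override a full chromosomal set. Unknown symbols warn and
are ignored.

Read evidence per contig (0-based half-open coordinates throughout):

* **mean coverage** — primary-alignment bases / contig length;
* **secondary fraction** — secondary records / all records (repeat
  signal);
* **junction-spanning reads** — distinct read ids with an alignment
  starting within `junction_window` (default 5000 bp, the standard 5 kb
  rule) of the contig start and one ending within the window of the end.
  Counted by read id so an origin-wrapping read split into two records
  counts once; secondary placements are excluded; supplementary SAM
  records (flag 2048) are treated as primary, since mappers may encode
  the wrap that way. For contigs shorter than two windows (small
  plasmids) the window shrinks to a quarter of the contig.
* **coverage-doubled blocks** — window depth profile (5 kb windows)
  thresholded against a baseline = 30th percentile of window depths.
  The 30th percentile, not the median, because at desk scale a planted
  87 kb duplication occupies a third of the contig and contaminates the
  median (a whole-chromosome average, as used on real data, would be
  untouched). Detection is seed-and-extend with hysteresis: a block needs
  one window ≥ 1.6 × baseline but extends through contiguous windows
  ≥ 1.35 ×; gaps ≤ 3 windows are closed; blocks < 3 windows are
  discarded. These choices were calibrated on seed sweeps (30/30 planted
  87 kb duplications recovered at ≥ 80% overlap, 0 verdict errors on 60
  uniform contigs) after the naive 1 kb-window/median variant proved
  noise-dominated at 25–30× simulated depth.

**Verdict**: circular iff junction reads ≥ `min_junction_reads` (default
3 — a guard against chimeric singletons; the minimum count is not
published and is configurable) and no coverage-doubled block of ≥ 4
windows overlaps a terminus window. A large collapsed repeat at the
junction makes apparent spanning reads untrustworthy (the unresolved-
chromosome situation); a short noise block must not veto otherwise clean
evidence.

## Core-SNP phylogeny with recombination masking

Variant calling aligns each query genome's fragments against a reference
replicon through the same reciprocal-match machinery (assemblies, not
reads, are the input). Within each reciprocal match the fragment is
realigned semi-globally on a padded window; when a gapless placement
explains the span essentially as well as the edit-optimal alignment
(mismatches ≤ edit distance + 4), substitutions are read columnwise —
edit-optimal paths re-express neighboring substitutions as balanced gaps,
which would shift calls. Coverage = union of matched reference spans;
`missing_fraction` = uncovered reference fraction (this package's reading
of "missing data").

The SNP matrix takes positions covered in **all** strains that are
polymorphic among the strains. Taxa above `max_missing` (default 0.31)
are excluded before analysis. Masking then iterates (≤ `recomb_max_iter`
= 5): rebuild the NJ tree; for each taxon flag reference windows
(`recomb_window` = 1 kb) whose taxon-specific SNP count reaches
`density_factor` (= 5) × that taxon's genome-wide SNP density × window,
with an absolute floor of 8 SNPs per window; set flagged sites to missing
for that taxon; stop when an iteration flags nothing new. The floor
matters on the second iteration: once an import is masked, the taxon's
genome-wide density collapses and a pure ratio threshold would fall below
Poisson noise and start eating clonal windows. The mask is monotone
non-decreasing and bounded by the iteration cap.

Trees are neighbor-joining (scikit-bio) on pairwise SNP differences
normalized by shared non-missing sites; pairs sharing no sites get the
saturation distance 0.75. Taxa are sorted lexicographically before the
join so output is independent of input order; negative NJ branch lengths
are clipped to zero; a zero-column matrix yields a star tree flagged
degenerate rather than an error. Likelihood inference is deliberately out
of scope — the matrix exports to FASTA/TSV so external ML tools can be
applied; NJ suffices for the recoverable claims (topology recovery,
masking effect).

The clade simulator plants imports as *shared donor haplotypes*: segments
with identical (start, end, donor divergence) are copied from one donor
sequence (root + divergence) into every recipient. A single-recipient
import merely lengthens one branch; a shared import into two non-sister
taxa is what actually distorts NJ topology, and is the configuration under
which masking demonstrably restores the true tree (RF 2 → 0).

## Taxonomy engine

Bands are half-open and lower-inclusive: [0,94) different species,
[94,95) ambiguous (the literature quotes both 94–96.5% and 95% as species
bounds; 95% is what reassignment practice applies, so the 94–95 gap is
surfaced rather than resolved), [95,97) same species / different
subspecies, [97,98) subspecies boundary zone, [98,100] same subspecies.
dDDH below 70% with ANI ≥ 95% yields a conflict annotation only.
`assign_strain` picks the type strain with maximal ANI (≥ 95% ⇒ that
species, boundary inclusive; ties all listed and flagged), otherwise
genus-level "*Bradyrhizobium* sp.". Synonymy detection scans a type×type
matrix for pairs ≥ 95% and assigns precedence by publication year from a
user-supplied metadata table — the engine does not encode nomenclatural
code rules. Transcribed decision-input tables (isolate ANI/AF matrix,
isolate-vs-type ANI matrix, the 31-strain reclassification worksheet)
ship as package data and drive the worked examples.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analysis
consumes: i.i.d. base composition at a target GC (chromosome 63%,
plasmids ~61%), uniform (Jukes–Cantor-like) substitution whose rate maps
1:1 onto target ANI, block insertions of fresh random sequence, large
repeat families at calibrated mutual identity (per-copy rate solved from
(1−e)² + e²/3 = identity), uniformly sampled reads with exact truth
placements (gamma-distributed lengths, shape 3), origin wraps split into
two primary records, secondary records emitted at homologous offsets of
repeat copies with ≥ 0.9 identity and ≥ 200 bp overlap, collapsed-
duplication reads clipped sharply at repeat boundaries, and clonal
evolution along a rooted tree with per-branch substitution probability
rate × branch length.

They do **not** emulate: real sequence composition (no genes, no codon
structure, no GC skew), indel-rich evolution, base-calling errors on
reads (alignments carry truth; no downstream stage consumes base errors),
chimeric reads, mapper artifacts beyond the secondary/supplementary
conventions described, GTR rate heterogeneity, or within-segment
mosaicism of recombinant imports. Passing tests therefore demonstrate
correctness of the *algorithms* under their stated models, not end-to-end
accuracy on real ONT data.

## Problem sizes and determinism

Default test and acceptance problem sizes — 200 kb pairs for ANI recovery,
80–250 kb replicons at 25–30× simulated depth for topology, 60–100 kb
genomes with 4–8 taxa for phylogeny — were chosen so each property is
measured with comfortable statistical margin while the whole suite runs in
well under a minute per module on one CPU. All randomness flows through
explicit integer seeds (numpy `default_rng`); identical seeds give
byte-identical outputs, and the pipeline writes an effective-config echo
(including the seed) with every run.

## Known limitations

* ANI here is a faithful fragment-reciprocal method but not a bit-exact
  reproduction of any specific BLAST-based tool; published matrices are
  treated as authoritative inputs to the decision engine rather than
  targets for re-derivation.
* AF is fragment-count-based; tools that report base-level aligned
  fraction will differ, especially on rearranged genomes.
* `missing_fraction` is uncovered-reference fraction; pipelines that
  define missingness per alignment column will exclude different taxa at
  the same threshold.
* The recombination scan is per-taxon versus the reference, not
  ancestral-state-aware; imports shared by *all* taxa (or present in the
  reference itself) are invisible to it.
* The SAM reader interprets only flags 0/16/256/2048 and derives spans
  from CIGARs; it is a consumer of minimal mapper output, not a general
  SAM validator.
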