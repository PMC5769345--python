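# Methods

## The data structure

A pan-genome is stored as a whole genome alignment: an ordered set of
locally collinear blocks (LCBs), each a gap-padded multiple alignment with
at most one row per genome, annotated with 1-based inclusive forward-strand
coordinates and a strand. Reverse rows store the reverse complement of the
forward genome slice, as XMFA does. Two invariants make the structure
lossless: per genome, the rows partition the genome exactly (complete,
non-overlapping coverage), and no column is gap in every row. Every genome
can therefore be re-extracted byte-identically at any time, and the
alignment can be serialized to standard XMFA and MAF.

The linear representation is the consensus genome: per block, a
majority-vote consensus with one character per alignment column (gaps never
win a vote, so consensus offset and alignment column coincide within a
block), concatenated with runs of 1000 `N` between blocks. The delimiter
runs keep any later alignment from crossing block borders. Two sidecar
indexes make the consensus reversible: the delimiter index (start and
length of every `N` run) and the gap index (per block and genome, every gap
run in alignment-column coordinates), plus a block table holding each
block's consensus interval and per-genome coordinates and a genome table
carrying names and replicon layouts. Genuine `N` runs in input genomes are
distinguished from delimiters only through the delimiter index, never by
looking at the sequence.

## One workflow iteration (adding a genome)

1. **Alignment step.** The consensus is aligned with the incoming genome.
   The built-in aligner seeds on k-mers (k = 15) that occur exactly once in
   each sequence (counting both orientations on the incoming side;
   palindromic seeds are skipped as orientation-ambiguous), merges seeds on
   common (anti-)diagonals into maximal runs and extends them while
   characters match exactly. Runs are chained by a
   longest-increasing-subsequence dynamic programme maximising anchored
   length minus 0.5 per skipped base; chains are extracted greedily, cut at
   links whose gap exceeds 200 bp on either sequence (so translocated or
   inverted segments inside a skipped gap stay available to later chains),
   and later chains may neither overlap nor bridge across an extracted
   span. Inter-anchor gaps are closed by banded global alignment with
   affine gaps (match 1, mismatch −1, gap open −4, gap extend −1; a gap run
   of length L costs −4 −L). The band is defined on the diagonal offset and
   doubles whenever the traceback touches a band edge, so returned
   alignments are optimal; terminal flanks that are too large to align
   within the cell budget are left unaligned rather than force-fitted.
   `N` mismatches everything including itself, in seeding, extension and
   scoring, which is what stops delimiter runs from attracting alignment.
   Unchained material becomes single-sequence blocks. Alternatively, any
   external aligner's pairwise XMFA can be ingested in place of this step.

2. **Merging step.** Single-sequence blocks of ≤ 10 bp are absorbed into a
   block holding a coordinate-contiguous row of the same genome (the 5'
   neighbour is preferred, then the 3' neighbour; reverse-strand receivers
   take the reverse complement at the matching text edge). Other rows of
   the receiving block are padded with gaps at the junction, so merging
   never changes the aligned-pair set or any genome sequence.

3. **Realignment step.** Sites where a gap run in one row is immediately
   adjacent to a gap run in the other ("consecutive gaps") are extended on
   both sides by the longer gap length, clipped at block borders,
   overlapping extensions are coalesced, and each interval is replaced by
   an optimal global realignment whenever the affine score does not
   decrease. Intervals whose optimal alignment would exceed the cell
   budget are left untouched.

4. **Resolving step.** Blocks whose consensus row overlaps a delimiter run
   are cut at the run's first and last consensus positions. A complete
   span yields three blocks; the middle keeps only the new genome's
   sequence with all gaps removed, a delimiter matched by gaps only is
   discarded, and consensus-side delimiter fragments are dropped as
   artifacts. Partial overlaps at a block edge are treated as the same
   operation minus the missing flank. New-genome middle fragments stay in
   place in block order.

5. **Leftover alignment.** Per genome, the forward representation of all
   single-sequence blocks is sorted by genome position and concatenated
   with 1000-`N` delimiters into one super-sequence; the two
   super-sequences run through the same align/merge/realign pipeline, the
   result is resolved twice (once against each super-sequence's own
   delimiter index), and surviving blocks are mapped back to original
   genome coordinates, replacing the single-sequence blocks they came
   from.

6. **Reconstruction step.** For each block holding consensus sequence, the
   source block and column range follow from the block table (consensus
   offset equals column within a block). The source rows are sliced over
   those columns, gap columns the pairwise alignment added to the
   consensus row are inserted into every original row, the new genome's
   row is overlaid, and the consensus row disappears. Blocks are ordered
   by consensus position. Pairs among previously aligned genomes are
   preserved exactly. A final merging pass absorbs short single-sequence
   fragments created by the resolving cuts.

7. A fresh consensus is built and the next genome can be added.

Removing a genome deletes its rows, cuts columns that became all-gap,
drops empty blocks, joins adjacent blocks whose genome sets, strands and
coordinates are contiguous, and renumbers genome ids compactly.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| delimiter length | 1000 bp | `N` run between block consensuses |
| anchor k | 15 | seed length; uniqueness required in both sequences |
| min chain support | 2 seeds | chains with less seed evidence are discarded |
| chain gap weight | 0.5 | per-base penalty for skipped sequence in chaining |
| max fill gap | 200 bp | chain links with larger gaps are cut |
| band width | 64 | initial gap-fill band; doubles on traceback contact |
| scores | 1/−1/−4/−1 | match/mismatch/gap open/gap extend |
| merge max length | 10 bp | single-sequence blocks up to this length merge |

The chaining constants were chosen so that, at the divergence this
structure targets (closely related strains), substitution- and small-indel
gaps are always bridged while rearranged segments larger than the fill
limit are never silently absorbed into a spanning chain. The merge
threshold of 10 bp matches the notion of a "short" LCB used in the
fragmentation statistics.

## Consensus voting

Votes are case-insensitive and output uppercase; any character outside
A/C/G/T (including `N` and IUPAC ambiguity codes) forms its own vote class
and never matches anything in alignment scoring. Ties are broken
lexicographically by default, which makes consensus construction
deterministic — identical alignment in, identical bytes out. A `random`
tie policy (one seeded stream over columns in block order) is available
where a randomized draw is wanted; order and tie noise is negligible for
downstream results, and reproducible builds are worth more than literal
randomness.

## Synthetic genomes and what passing tests mean

The fixture generator derives each genome independently from one random
ancestor (a star phylogeny) by applying, in order: large deletions (count
1, length uniform up to 7000 bp — about the largest single gene a deletion
should plausibly excise), translocations (count 1, 100–1000 bp),
inversions (count 1, 100–1000 bp), small indels (rate 10⁻³ per base,
geometric lengths with mean 3, insertions of novel sequence), and
substitutions (rate 10⁻² per base). Every surviving ancestor base's
position and orientation are tracked through all events, so the aligned-
pair truth between every pair of genomes is exact and enumerable — no
sampling estimator is involved; a pair counts only when its orientation
matches.

What the generator does not emulate: repeats and paralogy (the aligner
deliberately has no duplication handling — repeats enter the structure as
they appear in the genomes), a phylogenetic tree topology (star only),
compositional bias, and sequencing artifacts. Tests passing on these
fixtures demonstrate the bookkeeping (losslessness, reversibility,
coordinate bijections, add/remove symmetry) and alignment behaviour under
point and structural divergence; they do not certify accuracy on
repeat-rich real genomes, where the pluggable external-aligner backend is
the intended path.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere in the public surface; any
  half-open arithmetic is private. Empty rows use the Mauve "0-0"
  convention when parsing; they are never emitted.
* Aligned-pair sets are bit-packed into sorted int64 arrays (6 bits per
  genome id, 25 per position), which caps supported inputs at 63 genomes
  and 32 Mb per genome — comfortably above the intended strain-collection
  scale — and makes pair-set intersection the cost of a sorted merge.
* Banded alignment retries with a doubled band whenever the traceback
  touches a band edge and errors only when the band would exceed the cell
  budget; callers in the workflow degrade gracefully (flanks left
  unaligned, realignment intervals kept as-is) rather than propagate that
  error mid-build.
* Chain-extraction ties (equal anchored weight) resolve toward the smaller
  A-start; merge candidates prefer the 5' neighbour; both choices are
  deterministic.
* Multi-replicon genomes are aligned as one delimiter-joined
  super-sequence and resolved against its delimiter index, so no block
  ever spans a replicon border; genome-global coordinates (no padding)
  are used in the stored alignment and replicon layouts live in the genome
  table.
* An event in the simulator may never span the whole sequence; a model
  whose minimum event length cannot fit raises instead of silently
  shrinking.

## Known limitations

* No paralog or duplication modelling: repeated sequence is represented
  positionally, exactly once per genome copy.
* One leftover-alignment pass and one realignment pass per iteration — no
  iterative polish to convergence.
* The similarity used for genome ordering is a cosine over 8-mer count
  profiles; it stands in for alignment-free similarity statistics and the
  interface accepts precomputed pairwise scores where an exact external
  statistic is preferred.
* The index bundle layout (tab-separated sections) is this package's own;
  it is plain text so that pan-genomes diff cleanly under version control.
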