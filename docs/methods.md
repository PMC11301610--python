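# Methods

## Coordinate model

All internal coordinates are 0-based, half-open, on the somatic (MAC)
reference. An insertion is a zero-width junction indexed by the first
reference base *after* the inserted sequence — the native BAM frame — and
is converted to 1-based `start == end == junction + 1` only when writing
GFF3. Because a pointer repeat makes the excision junction ambiguous up to
a shift, every insertion is **left-normalized**: while the last inserted
base equals the reference base preceding the junction, the insertion is
rotated one base left. Normalization never changes the implied germline
sequence (property-tested), and both the caller and the synthetic truth
use the same canonical form, so junction comparisons are well defined.

Only primary alignments contribute anywhere; secondary and supplementary
records re-describe the same molecule and would double-count support.

## IES calling (milraa)

1. **Evidence.** Each CIGAR `I` operation of ≥ `min_insert_len` (default
   10 bp) in a primary alignment with MAPQ ≥ `min_mapq` (default 1)
   yields one insertion observation at the junction reached by walking the
   reference-consuming operations.
2. **Clustering.** Per contig, observations are single-linkage clustered
   on junction distance: a new cluster starts when the gap exceeds
   `max_cluster_dist` (default 3 for CCS, 10 for subreads — CCS junctions
   are near-exact while subread junctions jitter by a few bases). A read
   contributing several observations to one cluster is collapsed to its
   longest insert. Clusters whose member insert lengths are multimodal
   (consecutive sorted lengths differing more than 2-fold) are split by
   length class first, so two co-located elements of very different size
   cannot produce a chimeric consensus. Clusters with fewer than
   `min_coverage` (default 5) distinct reads are rejected and reported.
3. **Consensus.** CCS mode polishes the member insert sequences directly
   and takes the modal junction (leftmost on ties). Subread mode extracts
   each member's insert plus up to 100 bp of flanking read sequence
   (truncated at read ends, never padded), polishes those, and realigns
   the consensus to the reference window spanning the cluster ±(flank +
   50 bp) slack.
4. **Realignment.** Global affine-gap alignment (match +2, mismatch −4,
   gap open −4, gap extend −2; reference-window overhangs free), via
   Biopython's PairwiseAligner. The longest consensus-only run in the
   traceback is the insert and its reference coordinate the junction
   (ties: longest run, then leftmost). No run ≥ `min_insert_len` →
   cluster rejected with a reason, not an error.
5. **Annotation.** After left-normalization, the **pointer** is the
   longest prefix of the insert that also follows the junction in the
   reference; the element is **TA-bounded** iff that pointer is exactly
   `TA`. The per-site retention score is support / (support + excised
   spanners), where spanner classification uses the ±15 bp buffer rule
   below.

### Consensus algorithm

The consensus is iterative backbone majority polishing: the member whose
length is closest to the cluster median seeds the backbone; every member
is globally aligned to it with edlib; per backbone column, substitutions
and deletions are resolved by majority vote (ties in fixed A<C<G<T<N<del
order) and an insertion is accepted where more than half the members
insert, taking the most frequent (then lexicographically smallest)
inserted run. Two rounds; the result is a deterministic function of the
input list. With ≥5 members at ~10% i.i.d. error this removes virtually
all backbone-private errors; it has no partial-order graph, so complex
nested repeat structure within a cluster is resolved only as well as the
pairwise alignments allow.

## Spanning-read classification

A read **spans** a junction if its aligned reference interval covers
`[junction − buffer, junction + buffer]` (buffer default 15 bp); a
spanning read is **retained** if it carries an insertion of at least a
minimum length within the buffer of the junction, else **excised**. Reads
clipped inside the insert cover only one flank and are not spanning. The
minimum insert length differs by context: 10 bp for de novo evidence
(downstream clustering and coverage cutoffs absorb spurious short
insertions) but 20 bp for retention classification in milcor, which has
no downstream filter — 20 bp is far above the error-indel runs of noisy
subreads (geometric run of ≥20 has probability ≈ 2·10⁻⁶ per event) and
below the 26 bp minimum element length of the target regime.

milcor's per-site and per-read scores are two aggregations of this one
classification, so their tallies are exactly consistent on the same BAM
(asserted in tests). Binning thresholds are inclusive-outward: per-read
score ≥ 0.9 → MIC-like, ≤ 0.1 → MAC-like, otherwise ambiguous; reads
spanning no annotated site are unscored and omitted from binning.

## Breakage-site detection (miltel)

Soft clips of ≥ 24 bp are scored by the fraction of their positions
covered by exact occurrences of any rotation of the telomere motif
(default `TTGGGG`, configurable including multi-motif mixtures) or of its
reverse complement's rotations; clips with fraction ≥ 0.7 are clustered
per (contig, clipped side) with single linkage ≤ 10 bp and reported at
the modal breakpoint when ≥ 3 distinct reads agree. Exact rotational
matching (not an HMM or alignment score) is deliberate: at ~10% read
error roughly 55–60% of motif copies in a clip survive intact, which a
0.7 coverage threshold with overlapping occurrences still accepts, and
the cluster-coverage requirement removes what noise passes. The fraction
statistic is rotation-invariant and strand-symmetric (property-tested).

## Synthetic data (simdata)

`make_genomes` builds an i.i.d. MAC genome at 28% GC (AT-rich, typical of
ciliate somatic genomes) and plants IESs at junctions spaced ≥ 500 bp and
≥ 600 bp from contig ends. Each element is pointer + random core; for
TA-bounded elements (default all of them) the MAC junction is forced to
carry one `TA` copy and the insert starts with the other. Construction
guarantees the truth is canonical: the base after the pointer copy
differs between insert and reference (the pointer is exactly the planted
one) and the last inserted base differs from the base before the junction
(the planted placement is already left-normalized). The reinsertion
invariant — placing every planted insert back into the MAC reproduces the
MIC contig byte-for-byte — is verified before the generator returns.

`simulate_reads` draws reads from both genomes (lengths normal with mean
8 kb, sd 3 kb, floor 500 bp; 20× coverage each by default) and applies an
i.i.d. per-base error model: substitution 3%, deletion 3%, insertion
events 4% with geometric(0.5) lengths (10% total event rate, subread-
like). Each read is emitted with its exact true alignment to the MAC
reference — planted IESs as `I` operations, substitutions as `X`,
IES/telomere overhangs at read ends as soft clips — into a
coordinate-sorted, indexed BAM, so the calling pipeline is tested
hermetically without an external mapper; a FASTQ (reverse-strand reads
reverse-complemented) is also written for optional real-mapper runs.
Outputs are byte-identical for a fixed seed (single PCG64 stream; BAM
sorted with `--no-PG`).

What the generator does **not** emulate: chemistry-specific error
autocorrelation and homopolymer bias, genomic repeats and low-complexity
tracts (IES cores are i.i.d. random), IESs longer than the read length,
scrambled rearrangements, and chimeric reads. Passing tests therefore
demonstrate correctness of the calling logic under the stated rates, not
performance on repeat-rich real genomes; junction and assembly accuracy
on real subreads will be lower, especially where flanks are repetitive.

`evaluate` matches calls to truth one-to-one, greedily by junction
distance within a tolerance (closest first, ties leftmost), then scores
matched pairs by global edit alignment (edlib): exact sequence matches,
and matches within 1 mismatch and 1 indel base. On instances whose sites
are separated by more than twice the tolerance the greedy matching is
provably maximum (and is checked against an exhaustive oracle in tests).

## Problem sizes and defaults

The default simulation — 2 × 250 kb contigs, 100 IESs of 26–100 bp,
20× + 20× coverage, 10% error — is the regime the acceptance script and
the heavier tests run; it completes in well under a minute on one CPU and
is large enough for stable recall/precision estimates (±~3 percentage
points at n = 100). Coverage-monotonicity checks use a 150 kb / 30-IES
instance at 10× vs 30× MIC coverage.

## Other design notes

* The CLI accepts `--threads` for forward compatibility with contig-level
  parallelism but executes serially; results are by contract independent
  of its value.
* Clip evidence feeds only breakage-site detection; IESs overlapping
  contig ends are out of scope, as are deletion-type calls against an
  IES-containing reference.
* Per-cluster decisions (rejections and reasons) are reported in the
  cluster TSV and at debug log level; all output files embed the tool
  version and effective parameters in their headers.
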