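# Methods

This note documents the models and procedures implemented in `py1h`, the
assumptions behind them, the parameters that matter, and the numerical
choices made where the design was genuinely open.

## Reporter signal model

The unit of quantification is one colony on a 1536-format (32×48) readout
plate; each strain occupies a 2×2 quadruplicate block. From the image
stage every colony gets an area `A` (foreground pixel count) and an
intensity `I` (mean foreground pixel intensity after the cell-local
background level is subtracted; see below). Per plate:

- `I_min` — the minimum intensity over detected colonies on that plate.
  The plate is the unit of imaging, so `I_min` and the baseline are
  per-plate quantities; no cross-plate normalization is attempted beyond
  this.
- per-colony value `(I − I_min)·A` — a size-and-intensity composite in
  signal·pixel units.
- `empty_baseline` — the mean per-colony value over all empty-empty
  control colonies (neither prey vector expresses a TF).

A strain's reporter signal is `RS = agg[(I − I_min)·A] − empty_baseline`,
aggregating the quadruplicate by the **median** by default. The median is
robust to a single bad colony; the mean is available
(`aggregation="mean"`), and with it the mean RS over the empty strains on
a plate is identically zero — a property the tests assert. RS is invariant
to adding a constant to every colony intensity, since `I_min` shifts
identically.

From the per-strain scores of one bait × TF-pair series the interaction
indices are exact differences: cooperativity `RS_pair − RS_TF1 − RS_TF2`,
antagonism-1 `RS_TF1 − RS_pair`, antagonism-2 `RS_TF2 − RS_pair`.

**Quadruplicate uniformity.** A strain is "uniform" when ≥3 colonies were
detected and the coefficient of variation of the per-colony *raw signal
mass* `I·A` is ≤0.5. The CV is computed on `I·A` rather than on
`(I − I_min)·A` because the background-subtracted mass has mean ≈0 for
baseline strains, where a CV is meaningless; the raw mass measures the
same colony-to-colony consistency on a stable scale.

## Image stage

1. **Preprocess** — RGB reduced to luminance, rescaled to [0, 1] with a
   guard for constant images. Larger value = stronger blue/β-gal signal;
   for light plates with dark colonies use `invert=True`
   (signal = 1 − luminance). The camera-to-signal convention is
   configurable because it is hardware-specific.
2. **Crop** — bounding box of a fixed-threshold mask (default 0.1 of the
   rescaled range); idempotent; `blank_plate` error when nothing crosses
   the threshold.
3. **Grid detection** — a colony mask is built by subtracting a
   tile-percentile background (20th percentile per 16 px tile, smoothed
   and upsampled — robust to bright colonies, which inflate a plain blur)
   and thresholding at 5 robust sd of the residual noise (floor 0.03).
   The mask is projected onto each axis; projections are smoothed with a
   moving average of half the estimated spacing; colony centers are the
   rising-to-falling zero crossings of the projection gradient, refined to
   sub-pixel by local center of mass. Spacing = median inter-peak
   distance; origin and spacing are refit by least squares on the peak
   positions, and the full 32/48-line equidistant grid is registered at
   the shift capturing the most projection mass — this is what tolerates
   missing colonies. Fewer than `min_peaks` (default 8) peaks on an axis
   raises `no_grid_detected`.
4. **Segmentation** — per grid cell: local Otsu threshold, largest
   connected component, hole filling. Cells whose foreground/background
   contrast stays below 0.06 are declared empty (an Otsu split of pure
   noise, not a colony). This classical segmenter is deliberately
   dependency-light and deterministic, and is pluggable should a learned
   model be preferred.
5. **Measurement** — `A` = labeled pixel count; `I` = mean foreground
   intensity minus the mean of the cell's background pixels. Subtracting
   the cell-local background level keeps a smooth plate-wide intensity
   gradient from leaking into colony intensities — without it the
   empty-control RS spread is dominated by where each control sits on the
   plate rather than by colony variation. Colonies touching a *neighboring*
   cell are flagged `touching` (flagged colonies are excluded from
   scoring); touching the image border only means the crop clipped an
   outer cell and is not flagged.

Measured recovery on synthetic plates (asserted in the tests): grid
centers within 1 px of truth noise-free and 2 px at default noise; areas
within ±10% of the rendered truth; amplitudes within ±5% on interior
cells (border cells clipped by the crop get the ±10% area tolerance).

## Event calling

Activity quantization uses a robust z-score of a strain's RS against the
plate's empty-empty distribution: `z = (RS − median)/(1.4826·MAD)`. The
reference sample is the **per-colony** empty RS values (≈4× more values
than strain-level aggregates, hence a much stabler MAD; with 24 empty
strains the scale estimate is within ~10%). Default level bins: z<2
very_weak, 2–8 weak/moderate (cut at 4), ≥8 strong; moderate/strong
counts as "active". The bins are configurable: the corresponding
manual-curation step in a real screen has no unique numeric equivalent.

QC rejects a series (call = inconclusive) when any strain failed mating
growth, has <3/4 uniform colonies, is contaminated, or (optionally) lacks
sequence confirmation.

The calling rule is total over activity patterns (pair, TF1, TF2):

| pair | TF1 | TF2 | event |
|------|-----|-----|-------|
| + | − | − | cooperative |
| − | + | − | antagonistic_TF1 (mirror for TF2) |
| − | + | + | antagonistic_mutual |
| + | any active | | independent |
| − | − | − | none |

**1-AD modality.** With both reciprocal AD orientations tested, the
active/inactive 4-tuple (TF1-AD alone, TF1-AD+TF2, TF2-AD alone,
TF2-AD+TF1) resolves the binding modality via a mechanism-derived truth
table: (−,+,−,+) mutual cooperativity; (+,+,−,+) TF1 recruits TF2 (and
mirror); (+,−,−,−) sequestration of TF1 (and mirror); (+,−,+,+)
competition won by TF2 (the TF whose AD-tagged pair strain stays active
is the competitor; mirror symmetric); (+,+,+,+) independent; anything
else unclassified. The table is derived from the binding mechanisms, not
from any published figure, and round-trips exactly through the synthetic
screen generator. The 2-AD design maps cooperative → mutual cooperativity
and antagonistic → sequestration; everything else is indistinguishable.
When the two orientations disagree, the orientation showing a dependent
event (cooperative first, then antagonistic) determines the event — a
tie-break the assay itself does not dictate.

## Motif analysis

Scanning scores every window of length k as `Σ log₂(PWM_i[base]/0.25)`
(uniform background). Scores are discretized at 1e-4 bits per unit
(configurable); the per-window score is the exact integer sum of
per-position integerized log-odds, and the p-value `P(Score ≥ s)` over all
4^k background words comes from an exact dynamic program on the same
integer grid — so scanning, the p-value lookup and the score threshold
derived from `p ≤ 1e-4` are mutually consistent by construction, and the
DP matches brute-force enumeration exactly (asserted for k ≤ 8). A
zero-probability matrix entry makes the window unmatchable (score −∞,
reported p only at s = −∞, which returns 1). Both strands are scanned;
coordinates are always reported 0-based half-open on the forward strand.
PWMs whose maximum base probability is below 0.8 at *every* position are
dropped as low-specificity before scanning ("every position" is one
reading of an ambiguous rule; the alternative — any position below 0.8 —
would discard nearly all real PWMs).

**Core-motif merging.** Hits of one TF on one promoter are grouped
transitively when consecutive hits share ≥80% of the shorter hit's
nucleotides. Each group emits the n-way intersection if it is ≥4 nt;
otherwise the group drops one end member at a time — keeping the
contiguous (n−1)-run with the longest intersection, ties to the leftmost —
and the dropped member re-enters as a singleton (its own interval). A
final left-to-right sweep trims any residual overlap between emitted
cores and drops cores that shrink below 4 nt, so the output is always
pairwise non-overlapping with length ≥4 (property-tested on random hit
sets). Two TFs co-bind when they have cores within 10 nt edge-to-edge
(overlap = gap 0).

## Network randomization

The screen network is bipartite and directed (TF-pair → promoter).
Randomization performs double-edge swaps: two random edges exchange
targets; swaps creating a duplicate edge (or no-ops) are rejected.
"20,000 switches" counts *successful* swaps, with a retry budget of 100×
(whether published switch counts mean attempts or successes is ambiguous;
successes is the conservative reading). Degrees are preserved exactly by
construction, and the chain's proposal is symmetric, so with enough
switches the sampled networks are uniform over the degree-preserving
configuration space — verified against brute-force enumeration on a tiny
network (total variation < 0.05). The swap loop is numba-compiled;
10,000 randomizations of a 300-edge network with 20,000 switches each run
in ~20 s.

An edge overlaps the evidence when *both* TFs of its pair satisfy the
mode at the edge's promoter: peak summit in the promoter in any cell
line, in the same cell line, summits within 50 bp of each other
(|summit₁−summit₂| ≤ 50 on the same promoter), core motif anywhere, or
cores within 10 nt. Observed overlap is compared to the null sample via
`Z = (obs − mean)/sd` (sample sd, ddof=1) and a two-tailed normal p.
The two-proportion comparison uses per-group `SE = √(p(1−p)/n)` and a
pooled-variance z by default (unpooled by flag); no published variant
name forces either choice.

## Expression specificity and co-expression

Cluster-level expression is the per-cluster sum of per-cell normalized
expression plus a pseudocount of 1 (so every entry is strictly positive
and an absent gene scores as maximally uniform rather than undefined).
The specificity score of a row with fractions `f_c = Exp_c/ΣExp` is
`Σ f_c·log₂(C·f_c) = log₂C − H(f)` bits: 0 for identical expression
everywhere (returned exactly, via a constant-row check that sidesteps
floating-point residue), up to log₂C for single-cluster expression —
about 7.54 bits at C = 187 clusters. The entropy identity is the
independent oracle in the tests (agreement to 1e-9).

A gene is "expressed" in a cluster when its cpm strictly exceeds 10% of
its maximum across clusters (strict reading of an ambiguous ">10%"); the
10% rule uses pseudocount-free values — the pseudocount belongs to the
entropy score only. Simpson co-expression of two genes is
`|A∩B|/min(|A|,|B|)` over their expressed-cluster sets (the denominator
is the more specific gene's set; ties give the same result), undefined
and flagged when either set is empty.

## Paralogs and homology

Percent identity comes from a global pairwise alignment
(`Bio.Align.PairwiseAligner`, BLOSUM62, gap open −10, extend −0.5):
identities / full alignment length ×100 (gap columns included;
`denominator="shorter"` available). Homology expansion of known pairs
(X, Y): every A with id(A,X) ≥ cutoff and B with id(B,Y) ≥ cutoff adds
(A,Y), (X,B), (A,B), deduplicated as unordered pairs with provenance
known/homology; the cutoff can be a percentile of the off-diagonal
upper-triangle identities. Partner profiles are binary vectors with two
bits per shared tested partner (≥1 cooperative event, ≥1 antagonistic
event); similarity is Jaccard |AND|/|OR|, undefined when the union is
empty. Identity classes: <30 low, [30, 50] medium (closed, since the
published bins "<30", "30–50", ">50" leave the boundaries to the middle
bin), >50 high.

## Sequencing confirmation

A read survives when it is a primary alignment with score ≥ 0.9× the
trimmed read length and strictly fewer than 5% mismatches (AS and NM tags
of the upstream aligner; SAM parsed with pysam). Per well, an expected
target is confirmed when its surviving-read count is ≥1 and strictly
exceeds every non-expected target's count — ties are unconfirmed ("the
gene with the most aligned reads", singular). Wells expecting both a TF
and an empty vector evaluate each expectation over the same reads; both
must outrank all decoys. A TF-pair series is confirmed when TF1 and TF2
are confirmed in the pair well, TF1 + the AD2µ empty vector in the
TF1-empty well, and TF2 + the pGADT7 empty vector in the TF2-empty well.

## Synthetic-data generators

The generators define the study conditions for all tests:

- **Plates.** Colonies are flat-top disks (radius 6 px, spacing 20 px)
  with a 1-pixel anti-aliased rim; the true area is the count of pixels
  with ≥ half coverage, which the rim leaves exactly defined. Background:
  a linear intensity gradient of 5% of the maximum amplitude plus i.i.d.
  Gaussian pixel noise of sd 2% of the maximum amplitude. Colony
  amplitudes get 3% multiplicative jitter (colony-to-colony biological
  variation). Occupied blocks are spread evenly over the plate, as
  robotic array pinning does.
- **Screens.** Amplitude levels: baseline 0.12 (an unstained colony still
  reflects light), strong 0.85, weak 0.131. The weak level is calibrated
  to sit ~3 robust-z above baseline under the default noise model, i.e.
  genuinely intermediate: detectable but below the "active" cutoff. The
  2-AD event vocabulary (obligate/enhanced cooperative, TF1-/TF2-
  antagonized, independent, none) and the 1-AD modality patterns map onto
  these levels; 24 empty-empty control strains are interleaved per plate.
- **Motifs.** PWMs with dominant-base probability 0.85–0.95 per position
  (strictly positive everywhere); consensus sites planted by substitution,
  reverse-complemented on the minus strand.
- **Networks.** Each pair connects to 3 random promoters; each
  (TF, promoter) cell receives evidence with probability 0.15, boosted by
  the enrichment parameter when the TF's pair has an edge there;
  enrichment 0 gives an evidence set independent of the network.
- **Alignments.** Confirmed wells put ~95% of reads on target,
  unconfirmed wells concentrate reads on a decoy; ~10% of reads
  deliberately fail a filter (low score, excess mismatches, or secondary).

What the generators do **not** emulate: real agar texture, uneven
illumination beyond a smooth gradient, colony shape irregularity and
merging, camera color response, pinning offsets, plate-edge growth
effects; real PWM redundancy structure; linkage between ChIP evidence and
motif content; sequencing error profiles. Passing tests therefore
demonstrate correctness of the algorithms under controlled conditions and
graceful degradation under moderate noise — not robustness to every
pathology of real plate photographs.

## Problem sizes

The test suite and the acceptance script use: 100-event one-plate screens
(680×1000 px images); 10,000 randomizations × 20,000 switches for the
degree-preservation check and 300 randomizations per run for the
50-seed enrichment/null power checks; exhaustive enumeration for motif
p-values up to k = 8 and for the tiny-network null distribution; 1,000
random rows for the entropy-identity check. These sizes make the full
suite run in about a minute while keeping every check exact or
well-powered.

## Known limitations

- Grid registration assumes at least a handful of colonies per axis;
  plates with < ~8 populated grid lines per axis are rejected rather than
  guessed.
- Equivalence with any specific published analyzer's pixel-level outputs
  is not claimed: fixed thresholds, edge kernels and segmentation-model
  weights of such tools are not public, and a classical per-cell Otsu
  segmenter stands in for learned segmentation.
- The activity-level bins replace a manual curation step; they are
  explicit and configurable, but no claim is made that they reproduce any
  specific curator's judgments.
- The percentile cutoff for homology expansion depends on the TF universe
  supplied by the caller; published absolute cutoffs are reproducible only
  with the same sequence collection.
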