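# Methods

This package re-implements, as a tested pipeline over synthetic data, a
model comparison between two accounts of how repeated exposure changes
neural sequence representations: **associative learning** (the same
item–position code, strengthened — i.e. less noisy — with repetition)
and **recoding** (repetition triggers re-encoding into chunks).  The
experimental setting is a four-item sequence recall task: 14 distinct
permutations of four items, two of them *repeating* (practised 12 times
before the main phase and presented on 2/3 of the 72 main trials across
two runs), twelve *novel* (once per run).

## Sequence representation models

A sequence is an assignment of items to 1-based positions.  Three
distance models generate predictions over pairs of sequences:

- **Item–position (Hamming)**: `D_H(y, z)` = number of positions with
  differing items.  Range 0..L; a metric on fixed-length sequences.
- **Item–item (n-gram)**: `D_C = 1 − γ·|C_i ∩ C_j|` with
  `γ = 1/(L−(n−1))` and `C` the set of adjacent n-grams (bi-grams by
  default), *position-free*: FBI and BIN share the bi-gram BI.  Note
  that with repeated items the distinct-n-gram set is smaller than the
  window count, so `D_C(s, s) > 0` is possible; on the distinct-item
  permutations the experiment uses, identity holds.  Over the 24
  permutations the Hamming and bi-gram RDMs are negatively correlated —
  the two associative accounts make opposed predictions, which is what
  makes them distinguishable.
- **Item mixture** (null model): a sequence is the superposition
  `M = I·β` of its item codes with recency weights
  `β = (0, 1/6, 1/3, 1/2)`; distance is the correlation distance
  between mixture vectors.  Item codes are fixed orthonormal axes, so
  distances depend only on β and item placement.  Only the recency
  slope is implemented: a primacy slope of equal magnitude yields the
  identical RDM, and a flat slope is degenerate (all permutations map
  to one point).  The package takes the printed weight vector as
  primitive; the geometric rate form βₙ = αβ₀(1−θ)ⁿ cannot produce a
  zero first weight and is carried as metadata only.

Associative learning itself is the Dirichlet–multinomial conjugate
update: an items × positions count table whose row-normalised means are
the association weights μ (rows with no observations stay all-zero and
are flagged; an additive pseudo-count option provides the smoothed
posterior mean).

## The chunk (recoding) model

A chunking model is a pair (x, z): a **chunk set** x of n-grams and a
**mapping set** z assigning each observed sequence a *parse* — an
ordered tuple of contiguous spans covering positions 1..L (2^(L−1) = 8
parses for L = 4).  The inventory of possible chunks holds every
n-gram with no repeated item, 64 entries for four items, with prior
`p(c) = α·(n−k)!/n!` (α normalises over the inventory; each length
class carries equal mass, so α = 1/4, a uni-gram has prior 1/16 and is
exactly 3× more probable than a bi-gram).  Model evidence decomposes as

    log p(x, z) = Σ_{c∈x} log p(c)  +  Σ_tokens F·log η

— a one-off *code* cost for each chunk plus a per-presentation
*encoding* cost of F links at constant link probability η.  Default
η = 1/10, the reciprocal of the number of distinct contiguous spans of
a 4-item sequence; every comparison reported by the analysis scripts
and tests is robust over η ∈ {1/4, 1/8, 1/10}.

**Candidate space for the optimal model.**  Maximising the evidence
over unrestricted parse choices does not produce a learning dynamic:
because `p₁⁴η⁴ < p₄η` for any η ≤ 1, a one-shot sequence is always
"best" encoded as a fresh whole-sequence chunk, and every sequence —
novel or practised — would be chunked on sight.  Chunks are meant to
stand for *acquired regularities*, so the search restricts multi-item
chunks to sequences that have themselves been presented at least
`min_support` times (default 3); one-shot sequences keep their
primitive item codes.  Two laxer rules fail instructively: support by
substring occurrence in any repeated sequence lets novels borrow
shifted bi-grams from the practised sequences, and support counted
across different one-shot sequences is triggered by pigeonhole (twelve
permutations of four items must share adjacent pairs) — under either,
a shared bi-gram pays for itself and the novel/repeating distinction
collapses.  The threshold 3 sits between the multiplicity of a "novel"
sequence over the full experiment (2: once per run) and of a repeating
one (24); any value in 3..12 gives identical results for this design.
Within the admissible space the search is exhaustive over the parse
product when it has ≤ 20 000 combinations (always, for this design)
and deterministic coordinate ascent from the all-uni-gram encoding
otherwise; ties break toward fewer chunks, then lexicographically.

With that machinery, the experiment's structure pins the optimal model:
after practice it is exactly the two whole-sequence chunks; from the
first novel trial on it adds the four uni-grams and then never changes
— every repeating trial is encoded as one four-gram, every novel trial
as four uni-grams.  The fixed uniform-n reference models (1-gram-only,
2-gram-only, 4-gram-only) are evaluated by the plain evidence formula;
on the practice corpus the 4-gram model ranks first at every η tested.

**Chunk-code RDM.**  Trial dissimilarity is
`1 − |shared (chunk, start-position) codes| / max(|codes_i|, |codes_j|)`
— position-anchored and max-normalised, chosen so the three regimes the
model predicts fall out exactly: 0 within presentations of the same
repeating sequence, 1 between repeating and novel trials (no shared
codes by design), and Hamming/L between novel trials (whose uni-gram
codes coincide exactly where items match, i.e. novels look
item-position-coded under both accounts).

## Experimental design generation

Constraints: all 14 sequences distinct permutations; every pair
involving a repeating sequence at Hamming distance ≥ 3; the repeating
pair shares no item at a common position and no n-gram (n ∈ {2, 3, 4}).
The separation rule is deliberately scoped to repeating-involving pairs:
demanding Hamming ≥ 3 between *all* 14 permutations of four items is
combinatorially impossible — pairs below distance 3 are exactly the
transposition-related ones, and the largest transposition-free set of
permutations is an alternating class of size 12.  A `hamming_scope="all"`
switch exists for smaller sets.

Candidate sets are scored by the plug-in Shannon entropy (bits) of the
91 lower-triangle pairwise Hamming distances (maximise — a flat
distance distribution is the most informative RDM predictor; distances
are discrete so no binning is involved) and, as tie-breaker, the
absolute Pearson correlation between the item-position and item-item
RDM cells (minimise).  The Monte-Carlo search samples the repeating
pair uniformly over all permutation pairs and the 12 novels uniformly
over the pair-compatible permutations (uniform 14-subsets virtually
never satisfy the constraints), keeps constraint-passing samples, and
returns the best score; it raises rather than silently returning when
nothing passes.

Schedules: a practice prefix (each repeating sequence 12 times,
shuffled), then per run 12 sub-blocks of three trials — two repeating
(balanced to 12 presentations of each repeating sequence per run) and
one novel, shuffled within block; each novel sequence appears once per
run; a randomly placed quarter of main trials carries no response cue.
Phase timings (2.4 s per item, 4.8 s delay, 7.2 s response) ride along
as metadata only.

## RSA

Data RDMs are correlation distances (Eq.: `1 − r` of mean-centred
pattern rows) between trial patterns; model/data agreement is
Spearman's ρ over lower-triangle cells with average-rank ties — ties
matter, since the Hamming model takes ≤ 5 distinct values, so the tie
policy is fixed and tested.  Cells from degenerate rows (zero variance)
are recorded missing and dropped pairwise.  Same-sequence trial pairs
are included by default (distance-0 cells are informative for both
model families); masks make any cell subset, including exclusion of
repeat pairs, a one-argument change.

- **Noise ceiling**: upper bound = mean Spearman of each subject's RDM
  with the group-mean RDM; lower bound = the same with that subject
  left out.  The with-self mean slightly overestimates the attainable
  correlation, so lower ≤ upper; for independent random cohorts the
  lower bound is ≈ 0 while the upper retains a visible self-inflation
  (≈ 1/√n-ish) — worth knowing when reading ceiling plots.  Ceiling
  positivity is tested one-sided on Fisher-z transformed values at a
  threshold Bonferroni-corrected by the number of regions.
- **Group significance**: per subject, trial labels are permuted
  jointly over rows and columns of the data RDM (preserving its
  geometry) to give a null Spearman distribution with the true value
  appended; group-level null means are built by drawing one value per
  subject with replacement, `10/α` times, and the p-value is the rank
  of the true group mean (with the +1 correction, hence conservative).
- **Cross-condition (associative) test**: the item-position fit is
  computed over novel×repeating cells (`r_UR`) and within novel×novel
  cells (`r_U`); significance of `r_UR` uses the same permutation
  machinery restricted to the cross-condition mask.  Outcomes:
  *no-correlation* (repeating trials do not carry the item-position
  code; the noise comparison is meaningless), *repeating-noisier*
  (`r_UR < r_U`), *repeating-less-noisy* (`r_UR > r_U`, the
  associative-learning prediction).

## Model-free distance dynamics

Four cosine-distance series per subject (cosine, not correlation
distance — both live in one module under distinct names): between the
two repeating sequences' n-th presentations; between consecutive
presentations of the same repeating sequence (averaged over the two);
from each repeating presentation to the run's 12 novel patterns; and
between consecutive novel trials.  The presentation index is counted
within run and runs concatenated (per-run slopes averaged within
subject; an across-experiment axis is available).  Per-subject OLS
slopes enter a two-sided one-sample t-test at α = 0.05 corrected by
the number of regions.

## Interference / capacity

Codes are (item, position) bindings (two sequences share
`L − Hamming`) or position-free adjacent bi-grams.  Shared-code
histograms are exact enumerations over the 256-sequence
repeats-allowed space (bins follow `C(L,k)·(|A|−1)^(L−k)` for
distinct-item references; the reference itself is included in the
denominator by default, matching the enumeration size — the landmark
proportions 54/256 ≈ 21%, 12/256 ≈ 5%, 81/256 = 31.6% → 31% under
integer truncation are insensitive to that choice).  Capacity curves
draw learned sequences uniformly without replacement, replicated
(default 200–500 replicates); a sequence is *affected* once it shares
≥ 1 code with any learned sequence.  The unaffected proportion is
non-increasing per replicate by construction, collapses below 1% after
about five learned sequences under item-position coding (the
independence heuristic `(81/256)^m` puts it at 0.3% for m = 5), and is
strictly larger under the bi-gram code at every step.

## Synthetic cohorts

No neural encoding model is specified at the RDM level, so the
generator uses the simplest construction whose RDM provably tracks
shared-code counts: each code is an independent random voxel vector
with unit-variance coordinates, a trial's pattern is the scaled sum of
its codes plus independent Gaussian noise with a per-condition standard
deviation, and codes are redrawn per subject (RSA assumes shared
geometry, not shared patterns).  Generators: item-position codes
(16 vectors), chunk codes (the stationary optimal encoding: two
whole-sequence chunks plus position-anchored uni-grams — novel trials
are therefore *identical* in expectation under the two structured
generators, exactly as the theory requires), mixture (per-item vectors,
β-weighted), and null (pure noise).  All randomness flows from a single
seed; subject streams are split off the cohort generator in order.

What the generator deliberately omits: hemodynamics, autocorrelated
scanner noise, trial-estimation (LS-S) error structure, inter-subject
anatomical variability, and any behavioural coupling.  Passing tests
therefore demonstrate that the *analysis machinery* recovers planted
representational structure at realistic noise levels — not that real
cortical data contain such structure.

**Noise calibration.**  Condition noise levels are free parameters; the
validation suite fixes them once from a sigma sweep: "moderate" noise
per generator (σ = 6 item-position, 5 chunk, 3 mixture at 150 voxels)
places the leave-one-out noise ceiling near the 0.1–0.3 range typical
of single-subject fMRI RSA, and the associative scenario uses
(σ_novel, σ_repeating) = (4.0, 0.5) — a reduction large enough for the
cross-condition prediction `r_UR > r_U` to be detectable at 22
subjects, which is precisely the regime the noise-reduction account
needs to claim.  At mild asymmetry the structural variance difference
between the two cell masks dominates (novel×repeating Hamming values
span only {3, 4} by design) and the effect is invisible.

## Problem sizes and numerical choices

The analysis scripts and tests run the full study geometry (14
sequences, 72 main trials + 24 practice, 22 subjects, 150 voxels) with
permutation counts of 200–1000, group-bootstrap resolutions of
10/α for α between 10⁻³ and 0.05, and 100–500 interference replicates;
calibration loops use reduced cohorts (8 subjects, 40 voxels, 99
permutations, 200 runs).  Permutation Spearman values are computed by
one vectorised rank pass against the model ranks; `scipy.stats.spearmanr`
serves as the independent cross-check in tests.  Deterministic
tie-breaks are specified wherever a search could tie (chunk sets:
fewer chunks, then lexicographic).  Degenerate inputs (constant
patterns, flat mixtures, zero-variance slopes) raise typed errors or
return flagged results rather than NaNs.

## Known limitations

- The chunk-support rule is an operationalisation: the evidence alone
  cannot prefer the learned-vs-novel encodings (see above), and the
  threshold, while inert over a wide band here, is a modelling choice.
- The chunk-code RDM formula is one reasonable reconciliation of
  position-anchored codes with a max-normalised set overlap; other
  normalisations preserve the three regimes but differ off the
  landmark cells.
- The design search's cost function weighting (entropy first,
  cross-correlation as tie-breaker) is a choice; both objectives are
  computed and exported so other weightings can be ranked offline.
- Permutation nulls assume approximate exchangeability of trial
  labels; at very low noise the near-duplicate repeating-trial
  patterns violate this and mask-restricted tests become
  anti-conservative.  At the calibrated noise levels the null
  calibration test holds the nominal rate.
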