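# Methods

This note documents the models, numerical conventions, tunable parameters
and design choices behind `sparsehmm`, and what the synthetic test data
do and do not establish about behavior on real sequences.

## Model

The query is a core profile HMM: per-position match emission
distributions q_i over the 20 amino acids, one shared insert emission
distribution (equal to the background), and seven core transitions per
node (M→M, M→I, M→D, I→M, I→I, D→M, D→D).  Around the core sits a
HMMER3-style local-alignment wrapper with special states
S → N → B → (core) → E → C → T:

- entry B→M_i with probability 2(m−i+1)/(m(m+1)) (the uniform
  fragment-length convention);
- exit M_i→E allowed from every match state with probability one (the
  implicit local model; D states have no exit);
- N and C emit flanking residues under the background with a
  target-length model: loop = n/(n+2), move = 2/(n+2);
- no J state: one aligned region per query–target pair.  Multi-domain
  decoding is out of scope.

All DP values are natural-log odds ratios against the i.i.d. background
null (match emission score log(q_ic/bg_c); insert and flank emissions
score zero).  The textbook recurrences cover the core model; the
exact special-state parameterization is not printed anywhere
authoritative, so the HMMER3 convention above was adopted and is fixed by
the brute-force path-enumeration oracle in the test suite: Forward,
Backward, Viterbi and posterior decoding agree with explicit enumeration
of every legal state path for all m, n ≤ 3 to 1e-9 in probability space.

Background frequencies are the standard Swiss-Prot-derived amino
frequencies used throughout the pHMM literature.  Ambiguity codes (B, Z,
X, ...) map to a wildcard residue scored zero (background) everywhere.

## Numerics

Log-sum-exp accumulation uses `logaddexp` (max + log1p(exp(−|diff|)));
−inf is the additive identity and never produces NaN for finite inputs.
Within-row chains (the I-state recurrence, and its Viterbi/MEA max-plus
analogues) are vectorized by the substitution v_j = w_j + j·t, which
turns the affine recurrence into a running accumulate.  Traceback
recomputes predecessor comparisons with a 1e-9 tolerance (the chain trick
can differ from naive evaluation in the last ulp) and breaks ties
M > D > I, giving deterministic alignments.  Probability-space scaling is
deliberately not used; all computation stays in log space.

## Cloud search

Both passes keep three anti-diagonals resident (rows indexed (i+j) mod 3,
one column per target position) and record one bound — the lower-left and
upper-right cells — per anti-diagonal, so space is linear in m+n.  The
flood fill uses the Forward (log-sum) recurrence, not the Viterbi max:
pruning reads match-state values produced by the same recurrence the
sparse stage later completes.  Pruning parameters:

| parameter | meaning | default |
|---|---|---|
| α | per-anti-diagonal drop-off, nats | 12 |
| β | global drop-off (X-drop analogue), nats | 20 |
| γ | anti-diagonal length before pruning starts | 5 |

γ counts cells on the current anti-diagonal.  Pruning removes cells only
from the two ends of each anti-diagonal inward, because the bound
representation stores exactly one interval per anti-diagonal; interior
below-threshold cells survive.  The first anti-diagonals after the seed
carry only insert/delete mass (the seed's match value propagates
diagonally), which is one reason γ > 1 matters: with γ = 1 and finite
thresholds the fill would stop immediately.

`best_infwd` is the running overall maximum sampled when the pass
finishes the anti-diagonal containing the end cell (symmetrically
`best_inbkwd` at the begin cell's anti-diagonal); if the pass stops
early, the final maximum is used.

### Trimming and reorientation

The union of the two clouds may contain protrusions that cannot lie on
any begin-to-end path, and protrusions that leave gaps inside matrix
rows.  Trimming first clips each bound to the hull of cells reachable
from the previous two (then next two) retained bounds — the closest
interval approximation of graph reachability, which the test suite
verifies against a brute-force BFS oracle.  In the rare case where the
result still has a row gap (cells whose only support is a diagonal step
over a pruned anti-diagonal), a stricter sweep clips against single
adjacent bounds; both interval endpoints then change monotonically across
anti-diagonals, which provably forces one contiguous column run per row —
the property the flat sparse layout requires.  Reorientation converts the
trimmed anti-diagonal bounds to per-row intervals and raises rather than
silently repairing if contiguity were ever violated.

When the two clouds share no cell (a region of very low homology between
the seed anchors), the search falls back to the rectangle spanned by the
seed cells.

## Sparse matrix layout

Each row's column run is allocated with one extra slot on the left (for
same-row j−1 lookups) and widened to cover the dependency columns of the
row below, so every (i−1, j−1), (i−1, j), (i, j−1) lookup of every cloud
cell lands on an allocated slot; a shared sentinel slot serves lookups
into absent rows.  Retrieval for cell (i, j) is
`block_offset[i] + (j − row_offset[i])`.  Padding slots hold −inf
(probability zero) and are never written, which the tests assert
directly; with a full-coverage layout every sparse result equals the
dense reference within 1e-6.

## Score statistics

Forward null scores are modeled with an exponential upper tail at a fixed
rate of ln 2 per bit (1.0 per nat).  This is the standard conjectured
rate for Forward scores of local pHMMs, and it matches the slope measured
on this implementation's own null scores (≈1.0–1.25 per nat across tail
depths on 10^5 background sequences); fixing the rate rather than
fitting it keeps deep-tail extrapolation stable at the Forward filter's
1e-4 level.  The location is anchored per profile at the 96th percentile
of 1,000 simulated background-sequence scores (tail mass 0.04).

Seed-stage gapped scores use a Gumbel with the same fixed rate.  The
bulk of this null (a maximum over a handful of banded local alignments,
conditioned on k-mer double hits) is not Gumbel-shaped, so the location
is anchored on the upper-tail 95% quantile rather than by bulk maximum
likelihood; trials that produce no seed at all count as P = 1 and enter
the anchor quantile as −inf.  With these choices the empirical decoy
pass rates match the nominal filter levels (1%, 0.1% implied at the cloud
stage, 0.01%) within binomial error; exact distributional uniformity of
the shallow tail is not claimed — the calibration targets the filter
thresholds, where it is verified.

Filter cascade defaults: seed P < 0.01 → cloud-filter P ≤ 1e-3 → sparse
Forward P ≤ 1e-4; report threshold E ≤ 10.  E-values are P times the
number of target sequences searched.

### Cloud-filter comparability

Cloud search initializes the seed cell to probability one, so its running
maxima are measured relative to the seed anchor and omit the wrapper
costs a real Forward path pays.  Before converting the estimate
`A + max(best_infwd, best_inbkwd) + Z` to a P-value, the pipeline adds
the constant wrapper offset (N emissions to the begin column, the two
move transitions, the entry probability of the begin row, the begin
cell's emission, and the C tail past the end column).  On planted
homologs this makes the estimate track the sparse Forward score with a
median absolute difference under one nat.

### Bias correction

The composition-bias adjustment is a simplified null2 analogue: an
alternative null emission distribution is built as the posterior-weighted
average of the emission rows used across the aligned region, and the
log-odds of the aligned residues under that distribution versus the
background, clipped below at zero, is subtracted from the score.  It is
exactly zero when the weighted mix equals the background and positive for
low-complexity targets.  It is deliberately simpler than HMMER3's null2
(no omega prior, no per-domain envelope logic) and is labeled as such;
it over-penalizes strong true matches by a few nats, which the synthetic
benchmarks tolerate easily.

### Alignment boundaries

The aligned-region occupancy of target column j is
1 − P(emitted by N) − P(emitted by C); the reported target span runs from
the first to the last column with occupancy ≥ 0.5 (configurable) and is
widened, if necessary, to bracket the MEA path.

## Seeding

The internal seeder is a faithful-in-spirit stand-in for an external
k-mer prefilter, not a bit-compatible reimplementation: (i) diagonals
with two non-overlapping length-6 windows of profile match score ≥ 0
nats; (ii) X-drop ungapped extension (drop 20 nats) of the double-hit
anchor, threshold 0 nats; (iii) banded gapped local Viterbi (half-width
12) on the best four diagonals.  The score thresholds are deliberately
permissive — the calibrated P-value filter is the real gate — so that
essentially every pair receives a comparable seed score, which is what
makes the seed-stage null calibratable.  Only the best-scoring seed per
pair is analyzed downstream.  External seeds are read from m8-style TSV
(query, target, qstart, qend, tstart, tend, evalue; 1-based inclusive)
with query coordinates already in profile positions; their E-values are
converted to P-values by dividing out the originating database size.

## Synthetic data

The generator emulates the standard embedded-domain benchmark
construction at desk scale: family profiles with one dominant residue per
position (probability 0.6 plus the background share; transitions favor
M→M at 0.9), homologs sampled from the consensus at a default
substitution rate of 0.5 (≈52% identity) with 2% indels, spliced into the
middle of shuffled background sequences, plus pure shuffled decoys
(default lengths uniform on 80–160).  The homolog divergence default is a
deliberate desk-scale choice: a 50-position toy profile carries far less
information than a real protein family, so the ≤25% identity regime of
full-scale benchmarks is not detectable at this size by any method; 50%
identity makes detection non-trivial while leaving signal to detect.
Decoy sources are i.i.d. background rather than real shuffled proteins,
so compositional bias and repeat structure of real sequences are *not*
represented — passing tests establish algorithmic correctness and
statistical calibration under the modeled null, not real-database FDR.
A true positive must cover ≥50% of the planted interval and come from the
matching family; cross-family hits on embedded targets are neutral;
recall-0 is the fraction of trues ranked above the best false positive.

## Problem sizes used in the checks

Oracle equivalence runs on 100 random pairs with m, n ≤ 60 and
enumeration on all m, n ≤ 3; sparse-score fidelity on 50 planted pairs at
m = 100, n = 300; the filter-level checks calibrate on 1,000 nulls and
evaluate on 10^4–10^5 fresh decoys; the recall fixture uses 20 embedded
homologs among 200 decoys.  These sizes were chosen so the full suite
runs comfortably on a laptop-class single core.

## Known limitations

- One reported region per query–target pair; fragmented or multi-copy
  matches surface only through their best seed.
- A seed that lands outside the high-probability region can anchor a
  cloud that misses the optimal alignment; no recovery strategy is
  implemented.
- The bias correction is cruder than HMMER3's null2 and shifts scores of
  strong hits downward by a few nats.
- Calibration quality is tied to the background null; compositionally
  biased real databases will be anti-conservative without the bias
  correction.
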