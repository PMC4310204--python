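# Methods

## Problem and model

Plant microRNA precursors (pre-miRNAs) are 53–938-nt transcripts that
fold into stem-loop (hairpin) structures, from which a ~21-nt mature
miRNA is excised.  Distinguishing real precursors from the abundant
hairpin-like segments of coding sequence ("pseudo hairpins"), and then
locating the mature miRNA on a real precursor, is treated here as a
two-stage supervised classification problem over a 152-dimensional
structure-sequence descriptor:

1. **Precursor stage** — an RBF-kernel SVM separates real single
   stem-loop hairpins from pseudo hairpins using features of the whole
   hairpin.
2. **Mature-locating stage** — a second RBF-SVM scores *intercepted*
   sub-segments of a precursor.  A segment is a positive when it spans
   exactly from the start of the miRNA* to the end of the mature miRNA
   (so the duplex sits flush with the segment termini); segments cut at
   other positions are negatives.  At prediction time the best-scoring
   positive segment's 3'-terminal 21 nt are reported as the located
   miRNA.

Folding is delegated to ViennaRNA (RNAfold algorithms, partition
function included) at 37 °C; the engine version is recorded in model
metadata because MFE values drift between releases.

## The 152-feature descriptor

Six groups (9 MFE-related, 20 sequence-related, 6 mfold-related, 7
base-pair-related, 96 triple-related, 14 RNAfold-related; 69 of the 152
are the begin/end variants introduced for the interception setting).
Conventions that the literature leaves open were fixed as follows:

* **Stem region.** All positions between the outermost paired bases,
  excluding hairpin-loop interiors.  Bulges and interior loops within
  an arm count as stem positions ("mismatches").
* **21-nt windows.** `Avg_mis_num` tiles the stem region with
  non-overlapping 21-nt windows (`n_21nts = ceil(stem_len/21)`, last
  window may be short).  `Mis_num_begin`/`Mis_num_end` and the
  begin/end GC contents use the first/last 21 stem positions,
  truncating when the stem is shorter.
* **Triplets.** A window contributes when all three consecutive
  positions are stem positions and the center lies in the region
  (whole stem / first 21 / last 21 stem bases).  "(" and ")" are
  treated as one symbol, giving 4 nucleotides × 8 patterns = 32
  categories per region, normalised to frequencies.
* **MFE indices.** MFEI1 = (MFE/L)/GC, MFEI2 = (MFE/L)/n_stems,
  MFEI3 = (MFE/L)/n_loops, MFEI4 = MFE/tot_base_pairs,
  MFEI7/8 = MFE / GC fraction of the first/last 21 stem bases,
  MFEI9 = MFE/Avg_mis_num.  For MFEI5/MFEI6 this package uses the
  un-normalised counterparts of MFEI3/MFEI2 (MFE per hairpin loop, MFE
  per stem); the formulas are isolated in one function so an alternate
  convention can be swapped in without touching callers.
* **Thermodynamics (mfold group).** dS and dH come from a
  two-temperature finite difference of the fixed MFE structure's free
  energy: dS = −(ΔG(67 °C) − ΔG(37 °C))/30 K, dH = ΔG(37 °C) +
  310.15·dS, Tm = dH/dS − 273.15 °C.
* **Ensemble features.** dP = pairs/L, dG = MFE/L, dQ = Shannon
  entropy of the base-pair probability matrix / L, dD = ensemble
  diversity / L, NEFE = ensemble free energy / L, Freq = Boltzmann
  probability of the MFE structure, Diff = |MFE − EFE|/L.  dF, the
  compactness descriptor, is defined here as the probability-weighted
  mean pairing span divided by L.  z-scores (zP…zF) standardise each
  d-value against dinucleotide-preserving (Altschul–Erikson) shuffles
  of the sequence, each refolded with the partition function; the
  shuffle count defaults to 100 and is reduced (6–8) in the pipeline
  experiments below, which changes only the variance of the z features.
* **Guards.** Every zero denominator yields feature value 0 plus a
  logged guard event; vectors never contain NaN/Inf.  Scaling is
  min–max to [−1, 1] learned on the training matrix (constant feature
  → 0; no clipping of test values).

## Training-set construction

Pseudo hairpins are mined from CDS with randomly sized windows
(60–150 nt, widths drawn uniformly at sequential offsets, seeded).  A
window is kept when it folds into a single stem-loop with ≥19 base
pairs, GC fraction in (0.242, 0.825), |MFEI1| in (0.522, 1.39), at most
3 consecutive unpaired stem bases (the loop is excluded — any hairpin
loop would trivially violate the bound), at most 7 unpaired bases in
the best 21-nt arm window (standing in for the unknown mature
placement), and a stability score above threshold.  The stability model
is the fitted sigmoid f(x) = a/(b + e^{x·c}) with x = MFE/length,
a = 1.339e−12, b = 2.7783e−13, c = 45.843; f is monotone decreasing in
x and ranges over (0, a/b ≈ 4.8195).  The published threshold rule
"f(x) > −4.42" is vacuous because f is strictly positive; it is kept as
the (non-binding) default, with both threshold and direction exposed as
configuration, rather than silently replaced by a guessed sign
convention.

Mature-stage positives are produced by interception; negatives are
sampled sub-segments longer than 55 nt, *closed under pairing* (if a
position is included its partner is pulled in, then the interval is
extended to contiguity) so the stem-loop context survives, and distinct
from the positive interval.  The recommended positive:negative rate is
1:5 before SMOTE rebalancing to 1:1.

## Feature selection

Information gain of a continuous feature uses single best-threshold
discretisation (all midpoints of consecutive distinct values scanned);
IG is verified in the tests against an exhaustive brute-force scan.
SVM-RFE trains a linear-kernel SVM on the surviving features and
removes the feature with the smallest squared weight (ties: lowest
index).  The backtracking variant (B-SVM-RFE) re-admits, after an
elimination, the highest-gain eliminated feature whenever some
eliminated feature out-gains the weakest survivor — keeping the
re-admission only if the 5-fold cross-validated error strictly
improves.  At most one feature is re-admitted per step and each feature
at most once overall, which bounds the procedure at 2p eliminations.
Subset evaluation reports the 5-fold CV error with default SVM
parameters (LooErrorRate) and the independent-test error after a
(C, γ) grid search (TestErrorRate), both in percent; the selected
subset minimises TestErrorRate when a test set is supplied (ties:
LooErrorRate, then size), otherwise LooErrorRate.  The grid is the
LIBSVM-style C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} in powers of 4.

## SMOTE

Synthetic minority samples are x + rand·(y − x) for a random one of
the k = 5 nearest neighbours y and rand ∈ [0, 1); the ratio parameter N
grows the minority class to N× its original size.  All randomness is
seeded.

## Genome scanning

Queries (known mature miRNAs) are split into four nearly equal seeds
(first k mod 4 seeds one base longer).  Each seed is matched exactly
with KMP; each seed hit anchors a full-length Hamming comparison, and
sites with ≤2 mismatches (configurable; "fewer than 3") are kept — by
pigeonhole the 4-seed split is complete for any bound below 4.  Both
strands are scanned (reverse complement of the query; positions
reported on the + reference).  Around each site, windows of 60–150 nt
are enumerated on a 10-nt grid (step configurable), folded, and kept
when they are single stem-loops with the site inside the stem region.
Filtering applies the mining criteria with the scan-specific overrides:
GC between 30 % and 70 %, fewer than 6 non-complementary bases in the
mature window, and no gaps on the complementary strand (the pairing
partners of the mature window form a contiguous run).  Surviving
candidates go through the two-stage classifier; overlapping hits of the
same query collapse to the best-scoring one.

## Synthetic data: what it emulates and what it does not

The hairpin generator builds perfect or degraded inverted repeats
(controllable GC, arm substitution rate, planted 21-nt mature at the 3'
terminus, mirroring the canonical intercepted layout).  Low degradation
(≤0.05) emulates real precursors, high degradation (≥0.3) pseudo
hairpins.  These fixtures reproduce the *structural* contrast the
classifier exploits — pairing density, MFE indices, mismatch profiles —
but not the sequence-composition statistics, length distribution or
family structure of real miRBase precursors; the two synthetic classes
are more cleanly separable than real/pseudo sets, so passing the
end-to-end bar demonstrates that the pipeline is wired correctly, not
that the published accuracies transfer.  A useful empirical note: a
*perfect* high-GC repeat is more stable than real precursors and falls
outside the real-precursor MFEI1 window; moderately AU-rich, slightly
degraded hairpins are the realistic fixtures.  Short random RNA also
folds into some single stem-loop about half the time, so "fully
degraded" hairpins are rejected by the trained classifier rather than
by the single-loop test alone.

## Problem sizes and numerical choices

The bundled experiments use 300 + 300 generated hairpins (200 + 200
training, 100 + 100 held out), 6 shuffles for z-features, and
n = 400, p = 50, k = 5, effect = 2 SD for the planted-selection
recovery run; these sizes make the whole suite and the acceptance
script reproducible in a few minutes on one CPU.  Elimination ties in
RFE break to the lowest feature index; stratified CV folds are shuffled
with the recorded seed; zero shuffle-variance guards z-scores to 0; a
single sequence shorter than 2 nt zeroes the dinucleotide block.

## Known limitations

* MFEI5/MFEI6 and dF follow this package's documented conventions
  (isolated functions), which may differ from the original tools'
  unpublished formulas.
* Interception requires the miRNA* annotation; precursors lacking it
  are skipped rather than guessed.
* The mature-locating stage reports the 3'-terminal 21 nt of the best
  segment; 5'-arm matures are located only through the segment's
  orientation, not by duplex-offset modelling.
* No pseudoknots, no suboptimal-structure enumeration, no probability
  calibration of the SVM scores.
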