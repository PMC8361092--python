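# Methods

This note documents the models, the numerical choices, and what the bundled
simulator does and does not emulate.

## Coordinates and substrate semantics

Protospacer positions are 1-based, 1–20 from the PAM-distal end, PAM at
21–23. Sites are stored as given; reads declared (or simulated) in reverse
orientation are reverse-complemented once, in `quantify.orient_to_forward`,
so that downstream only cytosine is a substrate nucleotide (a position
called in the reverse frame maps through p → 21 − p). Only C→G conversions
enter the modeled outcome space; C→A/T bystanders are counted by
quantification (they exclude a read from the on-target numerator) but are
not modeled as outcomes. This binary choice — a C edited to A or T counts as
"not G-edited" at that position — is a package decision, made because the
proportion model treats each position as a Bernoulli "converted to G or
not".

## Read classification

Reads are aligned to the full amplicon with an affine-gap global aligner
(match 2, mismatch −2, gap open −6, gap extend −1, free end gaps; Biopython
`PairwiseAligner`). Any gap touching protospacer+PAM positions 1–23
classifies the read as an indel; otherwise the bases aligned to protospacer
positions 1–20 give the substitution map, recorded at reference-C positions.
Amplicons here are tens of nt, so full dynamic programming is used rather
than a banded approximation. This is a deterministic, documented classifier,
not a re-implementation of any external amplicon-analysis tool; quality
trimming and barcode demultiplexing are out of scope.

## Training-table assembly

Per replicate, indel reads are removed first; a replicate with fewer than
100 remaining reads is dropped (the threshold is strict: 99 fails; the
"more than 100× coverage" rule used by `window_filter` is likewise strict,
so coverage 100 fails there). Surviving replicates are summed per genotype, and one count is
added to every C-to-G outcome with at most two simultaneous edits over the
site's substrate Cs. Smoothing only the enumerated low-order space matters:
adding a count to every *observed* genotype as well would donate hundreds of
pseudo-counts at high coverage and visibly bias the labels. The order-2
default keeps every marginal and every adjacent pairwise cell nonzero —
which is exactly what the downstream models consume — while adding at most
k + k(k−1)/2 counts for k substrate Cs. The per-position efficiency label is
(smoothed count of reads G-edited at the position) / (smoothed total); the
denominator excludes indel reads because indel discard precedes assembly.
Coverage reported next to each label is the unsmoothed summed read count.

## Motif regression

Features are one-hot context encodings (position-major, A<C<G<T) at relative
offsets −k…−1, +1…+k around targeted Cs in the editing window (positions
4–7). The default radius k = 3 covers the 3-nt motifs known for CGBE
deaminases with one extra position of context on each side; k is
configurable because the informative radius is editor-dependent. The loss is
the fractional-response (quasi-binomial) cross-entropy — labels are
continuous efficiencies in [0,1], so no binarization — plus an L2 ridge of
1e-6. The ridge matters beyond numerics: the four one-hot columns of each
offset sum to the intercept column, so per-offset weight *levels* are not
identified, only within-offset contrasts; the ridge selects the mean-centered
representative, which is also what the logo matrix reports. Parameter
recovery should therefore always be judged on centered weights. The fit is
L-BFGS to gradient norm ≤ 1e-8 on a convex objective: deterministic, and
invariant to row order to ~1e-10.

## Efficiency ensemble

Architecture, per protospacer position: nine base networks (window sizes 7,
9, 11 — three independently initialized replicates each) over a shared
embedding table (A, C, G, T, PAD → ℝ¹⁶; PAD is a learned symbol used when a
window would leave the supplied sequence). Each base network is
256-ReLU → 128-ReLU → 1-sigmoid on the flattened embedded window; windows
are drawn from the full sequence, flanks and PAM included, because editing
at positions 18–20 plausibly sees PAM-proximal context. The ensemble output
is Σₘ λₘ yₘ with λ = softmax(α) over nine learned logits — the softmax makes
the "weighted average" literal (nonnegative weights summing to one) without
constraining the optimizer. One ensemble per position with a shared
embedding was chosen over a single shared network because positional effects
(the 4–7 window) are strong and per-position capacity is cheap at this input
width.

Training minimizes MSE over (site, substrate-C) pairs with 30% inverted
dropout on both hidden layers; non-C positions carry no loss. The
implementation is plain numpy with hand-written backpropagation and Adam
(float32). Defaults: lr 1e-3, batch 256, at most 60 epochs, early stopping
with patience 8 on the pooled validation Pearson R, and the checkpoint with
the best validation R is returned. When validation R is undefined (constant
labels), selection falls back to negative validation RMSE, and any epoch
with a defined R outranks all epochs without one. All randomness
(initialization, batch order, dropout masks) flows from one seed; two runs
with the same seed reproduce the validation curve exactly. With these
defaults a 5,000-site library (≈15,000 training pairs) trains in about a
minute on one CPU, stopping around epoch 35.

## Proportion model

Editing indicators X₁…Xₙ over a site's substrate Cs (genomic left-to-right
order) form a first-order chain: p(X₁)·p(X₂|X₁)⋯p(Xₙ|Xₙ₋₁). Marginals come
from the efficiency model; the dependence of each adjacent pair is the odds
ratio c = p₁₁p₀₀/(p₀₁p₁₀). Given margins (p_a, p_b) and c, p₁₁ is the
Plackett root of (c−1)x² − [1+(c−1)(p_a+p_b)]x + c·p_a·p_b = 0 chosen inside
the Fréchet bounds max(0, p_a+p_b−1) < x < min(p_a, p_b), with bisection on
the monotone map x → odds(x) as fallback when the discriminant is
numerically marginal (tolerance 1e-12). Conditionals follow by division;
forward propagation reproduces every input marginal to 1e-9 by
construction. Exact enumeration of the 2ⁿ patterns is refused above n = 12
(the chain sampler covers longer sites). Marginals at exactly 0 or 1 are
clipped to [1e-9, 1−1e-9].

c is estimated from the pooled smoothed training table, per pair of absolute
protospacer positions (pooling across sites; the correlation is treated as a
property of the editor and position geometry, not of the individual site),
and capped to [1e-4, 1e4] against smoothing artifacts. A pair present in a
query site but never observed in training falls back to the median of the
pooled estimates — under a globally planted correlation this is the right
prior, and falling back to independence instead demonstrably distorts
held-out outcome distributions; an explicit `default_c` overrides it.
Note that pooling across strata with heterogeneous margins is mildly
non-collapsible: with a planted c = 4 the pooled estimates center near 3.9.

## Synthetic libraries

The simulator emulates a paired guide/target amplicon screen: uniform-random
20-nt protospacers, NGG PAM (configurable), 10-nt flanks. True efficiency at
a substrate C is logistic(baseline + window boost·[position ∈ 4–7] + motif
terms), defaults baseline −2.5, window boost +1.5, and +0.8 for A or T at
offsets ±1 — planting the WCW-type preference at realistic magnitudes (peak
in-window WCW efficiency ≈ 0.65, out-of-window baseline ≈ 0.08). Reads per
replicate draw negative-binomial coverage (mean 1000, dispersion 10),
indels at rate 0.05, and correlated C→G edits sampled along the same
margins+odds-ratio chain the inference uses (planted c = 4), so the
generator doubles as the inference oracle; with probability 0.02 a read
converts one unedited substrate C to A/T (bystander). Each site owns a
random stream keyed by (seed, crc32(site id)), so per-site data are
independent of how many sites are simulated. Ground truth (p*, c*, rates)
is exported with every dataset.

Deliberately not emulated: sequencing error, PCR duplication, real genomic
flank composition, cell-state covariates (chromatin, repair activity).
Passing recovery tests on these libraries therefore shows the estimators and
models are correct and well-calibrated under their own assumptions — clean
reads, logistic sequence-context truth, first-order adjacent dependence —
not that real libraries meet those assumptions; on real data the attainable
correlations are far lower and label noise is structured.

## Evaluation protocol

Splits are by site (never by position) with largest-remainder rounding:
6:1:3 train/validation/test by default, 4:1 as the preset used when testing
against endogenous-style data. Trisection cross-validation puts every site
in test exactly once, holding out 10% of each fold's training portion for
validation. Benchmarks report Pearson R and RMSE either pooled over all
(site, position) pairs or as the unweighted mean of per-position
correlations (positions with fewer than 3 pairs or zero variance are skipped
and reported). Degenerate correlations return NaN rather than a fabricated
value.

## Problem sizes used in the shipped checks

The shipped test suite and `scripts/acceptance.py` run at sizes chosen to
exercise every claim in minutes on one CPU: 200 random chains for the oracle
comparison, 10,000 random bivariate joints, 200 single-C sites at ~2000×
coverage for the quantification statistics, 2,000 sites for motif recovery,
5,000 sites (suite) / 1,500 sites (script) for the neural-ensemble recovery,
and 80 sites at 5000× coverage for proportion recovery. These are the
package's own reference sizes; all scale with configuration.
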