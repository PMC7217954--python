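# Methods

## Decay model and normalization

The stability pipeline assumes first-order mRNA decay observed through an
actinomycin-D chase: transcription stops at t = 0 and abundance x(t) of a
transcript with decay rate k falls as x(0)·e^(−kt). Because the shutoff
depresses total cellular RNA, per-sample quantifications drift globally;
the pipeline removes this drift with the scale factor
s(t) = geomean(references at t)/geomean(references at 0) computed from
user-designated stable transcripts (defaults RPLP0, PGK1, TRAP1). The
remaining fraction R(t) = (x(t)/s(t))/x(0) is by construction exactly 1 at
t = 0 and invariant to any positive per-time-point global factor applied to
the whole matrix — this invariance is tested property-style.

Default time points are 0, 3, 6, 9, 12, 24 and 30 h. A transcript whose
t = 0 expression falls below `min_baseline_expression` (default 1.0 in the
matrix's FPKM-like units) is excluded as EXCLUDED_BASELINE rather than
normalized by a near-zero denominator; the default floor is deliberately low
and configurable.

## Kinetic fits, weighting and the nuisance amplitude

Three shapes cover immediate, delayed and incomplete decay:

* EXP: M(t) = e^(−kt)
* DELAY_EXP: M(t) = 1 until onset t0, e^(−k(t−t0)) after (t0 ∈ [0, 0.9·t_max])
* PLATEAU_EXP: M(t) = (1−c)·e^(−kt) + c with plateau c ∈ [0, 1)

Each candidate is fitted on the **untransformed** remaining fraction — never
on log(R), which would discard near-zero late points — by
`scipy.optimize.curve_fit` as A·M(t) with:

* **weights** σᵢ ∝ max(Rᵢ, 0.05): measurement noise on expression data is
  multiplicative, so residuals are treated as relative. The floor 0.05 keeps
  near-zero late points from dominating.
* **a free nuisance amplitude** A ∈ [0.2, 5]. The t = 0 measurement is as
  noisy as any other; forcing the fitted curve through R(0) = 1 propagates
  that one measurement's error into every point of the ratio and visibly
  biases the rate. In simulation at 10% noise CV the forced-amplitude fit
  recovers only ~88% of half-lives within ±20% whereas the free-amplitude
  weighted fit recovers ~95%; without noise A converges to 1 and all
  recoveries are exact. A never enters the half-life, which is defined on the
  normalized shape M.

Initialization uses the log-linear slope of the positive part of the curve
(rate started at the k ≥ 0 boundary for non-decaying series). Selection is by
small-sample-corrected AIC on the weighted residual sum of squares
(parameter counts 2/3/3), with `BEST_R2` available as an alternative.
Weighted RSS below 1e-8 counts as a numerically perfect tie so that a nested
model cannot beat an already-perfect simpler fit on optimizer round-off; ties
go to the model with fewer parameters. A candidate that fails to converge is
dropped (logged), not fatal.

The reported r² is the ordinary (unweighted) coefficient of determination of
the winning curve. For a constant series (zero total sum of squares) a
numerically perfect flat fit reports r² = 1 so that genuinely stable
transcripts reach the censoring stage rather than being discarded as bad
fits.

Half-life: the time at which M crosses 0.5 — ln2/k for EXP and for the decay
phase of DELAY_EXP (onset excluded: the half-life measures intrinsic
stability, not lag); for PLATEAU_EXP, −ln((0.5−c)/(1−c))/k when c < 0.5,
censored (+∞) otherwise. A winning rate below 1e-6/h is censored: the series
does not measurably decay within the 30 h window.

## Filter cascade and classification

Order fixed: (1) EXCLUDED_BASELINE (per condition, union); (2) EXCLUDED_FIT
if the transcript is missing from either condition or r² < 0.9 in either —
a half-life *ratio* needs both sides reliable; (3) EXCLUDED_RAPID if
t½ < 3 h in either condition, because the 3 h first sampling interval cannot
resolve faster decay; (4) EXCLUDED_CENSORED if either side is censored.
Survivors are called by the ratio t½(control)/t½(knockdown): STABILIZED at
≥ fold_change (default 2), DESTABILIZED at ≤ 1/fold_change, UNCHANGED
otherwise. Boundaries are inclusive and the comparison carries a 1e-6
relative tolerance so that a ratio mathematically equal to the boundary is
not pushed off it by optimizer round-off. Every input transcript appears in
the call table exactly once; the funnel counts (input → fitted → r²-pass →
rapid-pass → analyzable → changed) are non-increasing by construction and
survivors plus exclusions always sum to the input count.

## Over-representation test

For query size n, set size K (after intersection with the universe), overlap
k and universe size N, the p-value is the exact hypergeometric upper tail
P(X ≥ k) (`scipy.stats.hypergeom.sf(k−1, N, K, n)`), equivalent to the
one-sided Fisher exact test; only over-representation is tested. The default
universe is the set of transcripts that reached classification — conditioning
on analyzable transcripts is the conservative choice when the annotation-wide
background is unknown — and is configurable. BH FDR is applied across each
collection (α default 0.05). Note the exact test is conservative on sparse
supports: with small universes/sets the attainable p-values are coarse and
P(p ≤ α) can sit well below α; calibration checks therefore use large sets.

## Colocalization

Per channel: 2-D median filter (odd neighborhood, default 3; edges reflected)
then Phansalkar local thresholding with the original publication's
coefficients k = 0.25, r = 0.5, p = 2, q = 10 on [0,1]-scaled intensities,
window radius default 15 px; all four coefficients and the radius are
exposed. The local mean and population standard deviation use a square
window with reflection that duplicates the edge pixel. Foreground is strict
(intensity > t), so an all-zero image yields an empty mask.

Manders split coefficients follow the co-positivity definition: masked
intensities (zero outside each channel's mask), M1 = sum of channel-1 signal
on pixels where both masked channels are positive divided by its sum where
masked channel 1 is positive; M2 symmetric. A zero denominator yields an
undefined (NaN) coefficient, never an exception. The triple metric is
area-based on the binary masks — the percentage of |A∧B| pixels also in C —
not intensity-weighted, matching its reading as a "proportion of contacts".
Analysis is 2-D; volumetric stacks should be quantified slice-wise and
pooled.

## Synthetic data: what it emulates and what it does not

`simulate_decay_experiment` plants log-uniform half-lives in [3, 30] h,
exact fold-change pairs for the stabilized/destabilized classes (the draw is
restricted so both sides of a planted pair stay inside the range and remain
recoverable under the rapid-decay filter), multiplicative lognormal noise
parameterized by its CV (mean 1, so noise is unbiased on the natural scale),
a global per-time-point scale decline (default linear to 0.6 at 30 h,
emulating shutoff-depressed total RNA — this makes reference normalization
non-trivial rather than decorative), spiked-in non-decaying reference
transcripts, and log-uniform baselines (default 5–500). Planted changed
transcripts sit *exactly at* the fold boundary — the hardest case for the
classifier; under noise roughly half of them fall just below threshold,
which is why noisy-recovery checks assert direction (no stabilized ↔
destabilized swaps) and half-life accuracy rather than boundary hit rate.
Not emulated: sequencing-depth/length effects behind FPKM, count noise at
low expression, correlated library-level effects beyond the global scale
factor, transcript isoform ambiguity. Passing recovery tests therefore shows
estimator correctness under the stated noise model, not robustness to
quantification artifacts.

`simulate_coloc_stack` renders Gaussian blobs (σ = radius/2, truncated at
3σ) with deliberate contact pairs one radius apart; a chosen fraction of
contact midpoints receives a third-channel blob, whose disk provably covers
the whole contact lens, so the planted fraction is realized exactly on the
ideal masks. Truth records realized (post-placement) fractions since
discrete placement cannot hit arbitrary targets. The default additive noise
SD is 0.01: a perfectly flat zero background is degenerate for local
adaptive thresholding (after min–max rescaling every Gaussian tail pixel
beats a near-zero local threshold), and real detectors always impose a noise
floor. No PSF, optical sectioning or SIM reconstruction artifacts are
simulated.

`simulate_geneset_collection` draws each member of an enriched set from the
changed transcripts with probability `enrichment_strength`, uniformly
otherwise; strength 0 is an exact null generator used for calibration.

## Problem sizes and numerical choices

Validation and the reproduction script run at desk scale: 500 transcripts
for noiseless recovery, 2000 at 10% noise, 1000 null gene sets over a
10000-transcript universe (set sizes 500–2000, chosen large so the discrete
test's attainable p-values are dense near 0.05 — the expected null rate at
these sizes is 0.0457 by exact computation), 20 image seeds spanning planted
triple fractions 0–1 on 192×192 px scenes with 12 objects per channel.
These sizes exercise every code path with tight statistical margins while
keeping a full run under a minute.

## Known limitations

* Point estimates only: no confidence intervals on half-lives or ratios.
* The kinetic family covers monophasic decay with onset or plateau;
  biphasic decay would be attributed to the nearest family member.
* The rapid-decay floor (3 h) is tied to the default sampling grid; denser
  early sampling would justify lowering it.
* Reference-transcript noise is common-mode across a dataset: with few
  references the realized scale factor adds a shared error component that
  individual fits cannot remove.
* The enrichment stage tests over-representation of a fixed query; it is not
  a rank-based enrichment statistic.
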