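# stabiloc

Tools for asking two questions about an RNA-binding protein such as
Galectin-3: **which mRNAs does it stabilize or destabilize**, measured
transcriptome-wide from actinomycin-D chase time courses, and **where does it
sit relative to ER–mitochondria contact sites**, measured from multi-channel
fluorescence images. The package is aimed at wet-lab groups who have
post-quantification expression matrices (FPKM-like, one table per condition)
and microscopy stacks, and want a reproducible, scriptable pipeline instead
of one-off spreadsheets.

## What it computes

**mRNA half-lives and stability calls.** After transcription shutoff, each
transcript's abundance is converted to a remaining fraction

```
R(t) = ( x(t) / s(t) ) / x(0),    s(t) = geomean(refs at t) / geomean(refs at 0)
```

where the scale factor s(t) — the geometric mean of stable reference
transcripts (default RPLP0, PGK1, TRAP1) — removes the global RNA decline
caused by the shutoff itself. Three first-order kinetic shapes are fitted per
transcript by weighted nonlinear least squares and selected by small-sample
AIC:

```
EXP          M(t) = exp(-k t)
DELAY_EXP    M(t) = 1 for t <= t0,  exp(-k (t - t0)) after
PLATEAU_EXP  M(t) = (1 - c) exp(-k t) + c
```

The half-life t½ is where the selected shape crosses 0.5 (ln 2 / k for EXP).
A fixed filter cascade then runs per transcript pair: expression floor at
t = 0, goodness of fit r² ≥ 0.9 in both conditions, rapid decays
(t½ < 3 h) excluded, censored (non-decaying) excluded; survivors are called
**STABILIZED** when t½(control)/t½(knockdown) ≥ 2, **DESTABILIZED** at ≤ 1/2
(both thresholds configurable, boundaries inclusive).

**Regulon enrichment.** Called transcript sets are tested against GMT
gene-set collections with the exact hypergeometric upper tail
P(X ≥ k) — the one-sided Fisher exact test — against a universe of all
analyzable transcripts, with Benjamini–Hochberg correction across each
collection.

**Triple colocalization.** Each channel is median-denoised and segmented by
Phansalkar local thresholding, t = m·(1 + p·e^(−q·m) + k·(s/r − 1)). On the
masks and intensities it reports the Manders split coefficients
M1 = Σᵢ S1ᵢ,coloc / Σᵢ S1ᵢ (and M2 symmetrically, co-positivity definition)
for every channel pair, and the **contact fraction**: the percentage of the
ER ∧ mitochondria mask intersection that also overlaps the third channel.

**Synthetic data.** `stabiloc.simulate` generates chase experiments with
planted half-lives and classes, gene-set collections with planted
enrichment, and three-channel blob images with a controlled fraction of
contacts carrying a third-channel blob — all pure functions of their seed, so
every stage of the pipeline can be validated against known truth.

## Worked example

```
stabiloc simulate  --out-dir demo --seed 7 --n-transcripts 300 --noise-cv 0.1
stabiloc stability --control demo/control.tsv --knockdown demo/knockdown.tsv --out-dir demo/stab
stabiloc enrich    --calls demo/stab/stability_calls.tsv --gmt demo/genesets.gmt --out-dir demo/enr
stabiloc coloc     --tiff demo/stack.tif --out-dir demo/coloc
```

The stability run prints its cascade funnel (`demo/stab/summary.json`):

```
{"input": 300, "total_fitted": 300, "r2_pass": 252, "rapid_pass": 250,
 "analyzable": 249, "changed": 13, "stabilized": 7, "destabilized": 6, ...}
```

300 simulated transcripts at 10% measurement noise: 48 lose the r² ≥ 0.9
filter, 2 decay too fast to resolve, 1 does not decay, and 13 of the 249
analyzable transcripts show a ≥2-fold half-life change. (The generator
plants changed transcripts *exactly at* the 2-fold boundary, so under noise
roughly half of them land just below it — a deliberate worst case; none is
ever called in the wrong direction.)

The enrichment table (`demo/enr/enrichment.tsv`, top rows) ranks the planted
sets first:

```
set_name  universe_size  query_size  set_size  overlap  p_value   p_adjusted  neg_log10_p  significant
SET004    249            13          43        10       0.000002  0.000087    5.76         True
SET003    249            13          18        7        0.000004  0.000099    5.40         True
SET001    249            13          42        9        0.000021  0.000357    4.67         True
SET005    249            13          33        8        0.000034  0.000420    4.47         True
```

and the colocalization run reports (`demo/coloc/coloc.json`):

```
triple_percent: 51.3      # planted contact-coverage truth: 49.7%
manders ER|MITO: M1 = 0.232, M2 = 0.231
```

i.e. 51.3% of the ER∧mitochondria contact area overlaps the third channel,
within 1.6 percentage points of the generator's ground truth.

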