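# Methods

`fastfuse` implements the quantitative machinery behind a dominant-negative
titration / sensitized-emission FRET study of reovirus p10 fusion platforms:
a cluster/site model of cell–cell fusion, a pixel-wise NFRET pipeline, and
the normalization statistics of the supporting liposome and syncytium
assays. This note records the models, the defaults that matter, and the
design choices made where the problem was genuinely open.

## The cluster/site fusion model

Cell–cell fusion is attributed to `s` independent "fusion platforms" per
cell, each a plasma-membrane cluster of `n` p10 copies. A cluster is
poisoned by a single non-functional subunit, so when a fraction `f` of the
expressed protein is functional, the residual fusion activity is

    F(f) = 1 − (1 − f^n)^s

— the probability that at least one of `s` clusters is built entirely from
functional subunits, with all-or-none cluster behaviour and binomial subunit
sampling. Limits: `F(0) = 0`, `F(1) = 1`; `F` is strictly increasing in `f`,
nonincreasing in `n`, nondecreasing in `s`. With `s = 1` the model reduces
to the single-cluster binomial `f^n`; `predict_fusion` special-cases `s = 1`
to return that power exactly (the general expression loses the last ulp to
the double rounding in `1 − (1 − f^n)`).

Assumptions worth stating: functional and non-functional subunits mix
ideally (no preferential assembly), clusters have a single size `n` (fitted
`n` is an effective average), and sites act independently. `n` and `s` are
treated as real-valued effective parameters, not integers.

### Fitting

`fit_stoichiometry` minimizes the unweighted sum of squared deviations
between normalized activities and `F(f)` with `scipy.optimize.least_squares`
(trust-region reflective) inside the box `n ∈ [1, 30]`, `s ∈ [1, 100]`,
from 5 starts: the user init (default `(5, 3)`) plus four log-uniform draws
from the box seeded by the `seed` argument; the lowest-SSE solution is
kept. Optional `1/SEM²` weights are accepted. Standard errors come from
the Gauss–Newton covariance `inv(JᵀJ)·SSE/(m−2)` at the optimum — the
convention generic curve-fitting toolboxes report. Activities are
normalized so the `f = 1` condition averages 1, since `F` predicts a 0–1
fraction. Degenerate inputs (fewer than 3 distinct `f`, constant activity)
are rejected; non-convergence is returned honestly in the `converged` flag.

### Derived quantities

* `single_site_probability(f, n) = f^n` for integer cluster sizes; at
  `f = 0.5` this gives 0.78% for heptamers and 0.39% for octamers.
* `infer_cluster_size` inverts the binomial: continuously as
  `n = ln(residual)/ln(f)`, and over integers 1..`n_max` ranked by
  `|f^n − residual|`. A 0.85% residual at `f = 0.5` yields `n ≈ 6.88`,
  bracketed by the heptamer and octamer. Exact ties rank the smaller `n`
  first so both adjacent candidates are reported with the larger last.
* `half_max_fraction` solves `F(f*) = ½·F(1)` by Brent root-finding on
  `[0, 1]` (tolerance 1e−9; the root is unique by monotonicity) and reports
  the functional:non-functional ratio `f*/(1−f*)` raw and rounded. At the
  fitted `(n, s) = (8.74, 5.17)` this gives `f* ≈ 0.789`, a ratio of
  3.73 ≈ 4:1.

## Pixel-wise NFRET quantification

Three aligned channels are acquired per cell: donor (donor ex/em), acceptor
(acceptor ex/em) and FRET (donor ex, acceptor em). The pipeline:

1. **Preprocess.** Each channel has a scalar background subtracted (clipped
   at zero) and is blurred with a Gaussian kernel; the identical operation
   is applied to all three channels. Background defaults to the per-channel
   median (50th percentile), which is unbiased while signal covers a
   minority of the field; an explicit region mean or a known constant
   offset may be given instead — the constant form is required for diffuse
   (cholesterol-depleted) cells, where the whole frame carries signal and
   no image statistic can see past it. Blur sigma defaults to 1 px.
2. **Spectral bleed-through.** From single-fluorophore controls, per-pixel
   ratios `r = I_fret/I_source` are fitted against source intensity as a
   constant, linear, or exponential `a·exp(b·I)` model (`b = 0` recovers a
   constant). Pixels below a low-intensity cutoff are excluded: near the
   background the ratio is noise-dominated and biased upward (the offset
   left by background subtraction enters numerator and denominator
   asymmetrically). The default cutoff is 50 detector units — ten times the
   read noise of the synthetic images — chosen because at a 2-sigma cutoff
   the constant-SBT estimate was inflated roughly two-fold on synthetic
   controls. At least 1,000 pixels must survive the cutoff.
3. **NFRET.** Per pixel, corrected FRET
   `Fc = I_fret − bt_d(I_d)·I_d − bt_a(I_a)·I_a`, floored at zero (NFRET is
   a nonnegative interaction index and the 8-bit quantization requires it),
   then `NFRET = Fc/√(I_d·I_a)`. The square-root normalization makes the
   index invariant to a common detector gain. Pixels with donor or acceptor
   at or below `min_intensity` (default 5 DU, ~3.5 sigma of the residual
   background noise after subtraction and blur) are masked invalid.
4. **Histogram.** Valid pixels are quantized 8-bit style into 256 bins over
   the display range (0, 10) — bin width 10/256 = 0.03906 NFRET units.
   Values beyond the range saturate into the end bins.
5. **Mixture fit.** Sums of k = 1..4 Gaussians are least-squares fitted to
   the bin counts (amplitudes ≥ 0, sds > 0, means confined to the occupied
   support — an unconstrained broad component centred below zero can
   otherwise win the dominance rule). Components are seeded greedily (each
   k starts from the k−1 solution plus a component at the largest residual)
   with analytic Jacobians, and only the occupied bin range is fitted —
   empty far bins carry no shape information, though R² is still computed
   against all 256 bins. The fit with the highest R² is selected. mNFRET is
   the mean of the largest-area component (ties to the larger mean); the
   pixel amplitude is that component's fitted peak height. Histograms with
   fewer than 8 occupied bins cannot support a mixture fit and raise by
   default; `summarize_image(..., on_narrow="pixel_mean")` lets
   FRET-negative images (which routinely collapse into a few near-zero
   bins) report their pixel-wise mean instead.
6. **Condition summary.** Per-image mNFRETs are summarized by median, SD,
   min and max pooled over all images (the box-plot statistics), and by a
   headline mean taken over experiment means (the pooled mean is also
   reported; which aggregation the original analysis used is ambiguous, so
   both are emitted with experiment-wise as default). Pixel-amplitude error
   is propagated within each experiment as `SD/√n` and across `k`
   experiments as `√(ΣSEᵢ²)/k` — a defined, testable reading of
   "propagated within and across experiments"; the same rule drives the
   syncytial index. The reference design is 10 images per condition in two
   experiments (20 images).

A Pearson/Manders colocalization helper is included as plumbing for
scoring co-clustering on synthetic two-channel images; it is not part of
the NFRET quantification.

## Assay statistics

* **Lipid mixing.** `%LM(t) = 100·(F(t) − F0)/(F_MAX − F0)`, the standard
  dequenching normalization between a baseline and a fully diluted
  reference liposome population. It is affine-invariant (joint shifts and
  rescalings of F, F0, F_MAX cancel) and strictly monotone in F when
  `F_MAX > F0`. Both the full time series and the endpoint are emitted.
* **Syncytial index.** Per-experiment mean and SEM over fields (design:
  5 fields per well, 3 experiments), overall mean = mean of experiment
  means, overall SEM = quadrature of within-experiment SEMs divided by the
  number of experiments (reducing to the single-experiment SEM at k = 1).
  The alternative (SD of experiment means) is deliberately not the default.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume; all randomness flows from a single integer seed through
`numpy.random.default_rng`, and identical configurations are bit-identical.

* **Titration curves**: `F(f) + N(0, sd)` floored at zero on an 11-point
  grid `f = 0, 0.1, …, 1`, one replicate per point in each of three
  experiments; default noise sd 0.03 (a few percent of the full activity
  scale, matching well-behaved syncytial indexing).
* **FRET images** (256×256): punctum count ~ Poisson(density·area) with
  density 0.004 px⁻² (~260 puncta — a densely decorated membrane while
  keeping puncta resolvable), positions uniform, lognormal peak amplitudes
  (mean 500 DU, CV 0.3), Gaussian PSF sigma 1.5 px. Scenarios: interacting
  (co-positioned donor/acceptor puncta; FRET channel receives a true
  sensitized signal `E·donor` with `E = 0.3`; a `√(donor·acceptor)`
  alternative is available since no forward model is canonical),
  non-interacting (independent punctum sets, SBT only), donor-only /
  acceptor-only (SBT controls), and diffuse-depleted (uniform fluorophore
  of matched total flux, no FRET — the cholesterol-depletion phenotype).
  All channels add a 100 DU offset and 5 DU Gaussian read noise (optional
  Poisson shot noise, off by default — no acquisition noise statistics were
  available to match), clip at zero and saturate at the bit depth. Ground
  truth is emitted with every batch.
* **Lipid traces**: `F(t) = F0 + extent·(F_MAX − F0)(1 − e^{−rate·t})`
  plus Gaussian noise, so the %LM endpoint approaches `100·extent`.
* **Field counts**: Poisson draws per field, 5 fields × 3 experiments.

What the generator does **not** emulate: real optics (Airy PSF, chromatic
offsets), cell morphology and segmentation, intensity-dependent shot-noise
statistics by default, photobleaching, or acceptor-channel FRET losses.
Passing tests therefore demonstrate the pipeline's correctness and
sensitivity under its own stated model of the data, not performance on real
micrographs.

## Problem sizes

The parameter-recovery study refits 100 independent simulated titrations
(33 points each); the imaging comparisons use 10 images per condition in
two experiments of five, with 3 control image sets per SBT model — the
same condition sizes the reference imaging design prescribes, and small
enough to run in seconds to a couple of minutes on one core.

## Known limitations

* The fitted `n` is an effective cluster size; heterogeneous cluster-size
  mixtures are out of scope.
* SBT models are fitted marginally per fluorophore; cross-terms between
  donor and acceptor bleed-through are not modelled.
* R²-based mixture selection always prefers more components when they
  reduce residuals even marginally; mNFRET is robust to this because it
  reads only the dominant component.
* No absolute FRET-efficiency calibration: NFRET is a comparative index.
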