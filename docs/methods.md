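# Methods

## Scoring model

The assay measures, at each pixel, how far along the 18S-complementary
footprint (c18RNA) the surface-bound fragments extend. Four probes sit
at increasing distances from the capture site; a fragment produces
signal in round *i* only if it spans probe *i*'s site. The score
converts the four probe images into a 0–10 integrity number:

1. **Threshold.** `T = quantile(P0, q)` — a single scalar taken from the
   intensity distribution of the background autofluorescence scan,
   applied in per-pixel arithmetic. A per-pixel quantile of a single
   image is ill-defined, so the scalar reading is the only one that
   makes the subtraction exact. `q` defaults to 0.75; 0.30 is the
   recommended preset where cells are expected to hold little total RNA
   (lower threshold, more pixels retained).
2. **Normalization.** `N = P1 − P0 − T`. Pixels with `N ≤ 0` carry no
   footprint detectable above background-plus-threshold and are masked,
   not set to 0 — background must not dilute medians, and renderers draw
   masked pixels in a background color outside the score colormap.
3. **Ratios.** `R_i = (P_i − P0 − T) / N`. Subtracting both `P0` and `T`
   in the numerator makes `R₁ ≡ 1` algebraically: probe 1 is the
   self-normalizing reference that defines full detection, and — on a
   correctly registered stack — `R_i ≤ 1 + noise` for every probe.
   Negative ratios are floored at 0 before summation (signal below
   background carries no evidence of an intact footprint).
4. **Scale.** Each probe contributes up to 2.5 points:
   `sRIN = 2.5 Σ clip(R_i, 0, 1)`. This reproduces the interpretable
   levels 10 / 7.5 / ≤5 for 4 / 3 / ≤2 detected probes and bounds the
   heat map at 10. The per-probe clip (rather than clipping the final
   sum) is this package's choice among the readings consistent with
   those levels; the unclipped sum is kept alongside because its excess
   over 10 is diagnostic (below).

### Misalignment diagnostics

Only inter-round misregistration can push the unclipped score above 10
on a noiseless stack (a probe ratio exceeding the probe-1 reference at
the same pixel). Pixels with `raw > 10` are therefore flagged, excluded
from medians and positive-pixel counts, and summarized spatially: the
image is partitioned into `G × G` cells (default `G = 8`), expected flag
counts are proportional to per-cell valid-pixel totals, cells without
valid pixels are excluded and cells with expectation < 5 are merged with
their neighbor in scan order (the standard chi-square validity rule —
no rule is inherent to the assay), and a chi-square goodness-of-fit
p-value is reported. A uniform flag distribution indicates benign
residual error; clustering means the manual alignment should be redone.

Near the validity boundary (`N` barely positive) sensor noise alone can
occasionally flag pixels; at the default noise level this affects well
under 1 % of valid pixels and the flags are spatially uniform, so the
uniformity test is the meaningful readout, not the bare count.

### Sample summaries

A sample's value is the mean over technical replicates of the median
sRIN across valid, non-misaligned pixels. Medians exclude masked pixels
by construction (a decision: including background-level pixels as zeros
would conflate tissue coverage with integrity).

## Quantile and other numerical conventions

* Quantiles use linear interpolation between order statistics (numpy's
  default), fixed so results are bit-reproducible.
* Coordinates are 0-based `(row, col)`; crop rectangles half-open.
  Only integer-pixel translations are supported — the assay's images are
  aligned by eye or by whole-pixel phase correlation, and subpixel
  resampling would smear the per-pixel arithmetic.
* Scanner gain is metadata only; the assay requires one gain for all
  rounds, so mismatched gains warn rather than rescale.
* Score TIFFs store `sRIN × 1000` as 16-bit with a validity-mask image
  alongside; the bit depth of the assay's own exports is not dictated by
  the protocol, 16-bit is this package's fixed convention.
* Heat maps always span 0–10 (no per-image autoscale) so maps from
  different samples are visually comparable.

## Synthetic data generator

The simulator emulates the data-generating process far enough to
exercise every pipeline stage with known truth:

* **Tissue phantom.** Gaussian-blob cells (default 80 blobs on a
  128×128 grid, widths 2–5 % of the frame) give a relative cell density
  `D ∈ [0, 1]`; degradation profiles are `uniform`, `gradient`
  (left-to-right ramp), or `patchy` (smooth lognormal variation plus
  necrotic islands thresholded to cover a target fraction of tissue
  pixels). Necrotic pixels contain cells but no intact RNA.
* **Fragment model.** Fragment length is exponential with spatially
  varying mean `μ` (nt) — the simplest single-parameter family with
  monotone degradation. The probability a footprint reaches probe *i* at
  distance `d_i` is `p_i = exp(−d_i/μ)`. Default probe distances
  (100, 600, 1100, 1600 nt of an 1870-nt molecule) are evenly spread
  placeholders, configurable to real assay coordinates.
* **Image formation.** `P0 = b₀ + b₁·D + ε`, `P_i = b₀ + b₁·D +
  A·D·p_i + ε`, with Gaussian sensor noise `ε`, flooring at 0 and 16-bit
  quantization. Defaults (`b₀ = 200`, `b₁ = 300`, `A = 2000` FU,
  `σ = 20` FU ≈ 1 % of full signal) emulate a 16-bit fluorescence
  scanner with strong tissue contrast; Poisson shot noise and optical
  blur are deliberately omitted — they do not change what the scoring
  arithmetic is tested for.
* **Ground truth.** Because probe 1 is the scoring reference, the
  quantity the assay estimates is the detection profile *relative to
  probe 1*; the recorded truth is `true_srin = 2.5 Σ p_i/p₁`
  (equivalently `2.5 Σ exp(−(d_i−d₁)/μ)`). With background and noise
  switched off, scoring a rendered stack reproduces this truth to
  16-bit quantization accuracy at ≥99 % of cell pixels — the end-to-end
  identity the test suite asserts. With realistic background, the
  scalar threshold `T` is also subtracted inside each ratio, which
  biases intermediate ratios downward (strongly so near the detection
  limit). That conservatism is a property of the scoring method itself,
  not of the simulator; rank-based comparisons (ladders, correlations)
  are unaffected.
* **Degradation ladder.** Five samples with log-spaced mean fragment
  lengths from 5000 nt down to 150 nt (far above to well below the
  outermost probe distance), three replicate phantoms each. The bulk
  proxy `2.5 Σ P(L ≥ d_i)` shares the sRIN functional form and scale; it
  is *not* the electrophoresis RIN algorithm, whose nonlinearities (e.g.
  the behavior of mixed intact + degraded samples) it does not
  reproduce.

All randomness flows from explicit integer seeds; identical
configurations are bit-reproducible, including the CLI's file outputs.

### What passing tests do and do not show

The phantom has no optical point-spread, no probe-specific
hybridization efficiency differences, no bleaching across rounds, and
misregistration is a rigid integer translation. Tests passing on it
certify the scoring arithmetic, masking, flagging and summary logic —
not robustness to optical artifacts or non-rigid tissue deformation in
real scans.

## Statistics

* **RIN–sRIN correlation.** Pearson r on paired (bulk, averaged sRIN)
  values; `t = r√((n−2)/(1−r²))` on `n−2` degrees of freedom, two-sided
  p (the convention of R's `cor.test`). Five samples give df = 3. Raw
  replicate medians enter unrounded.
* **Hybridization efficiency.** Arithmetic mean fluorescence within each
  capture area, per probe — one estimate per (probe, area).
* **Positive-pixel fractions.** "Positive" for probe *i* means
  `R_i > 0`, i.e. signal above `P0 + T` — the scoring threshold reused
  as the positivity criterion, since no separate numeric definition is
  inherent to the assay. Fractions are relative to probe 1; misaligned
  pixels are excluded.
* **Exon/intergenic ratio.** A pure count ratio (annotated / discarded
  reads); read processing itself is out of scope.

## Problem sizes

The shipped tests and the acceptance script run the ladder experiment at
128×128 pixels with 3 replicates per sample and property suites at
32–96 px frames; these sizes give stable medians (the ladder correlation
varies by < 0.01 across seeds) while keeping the whole suite in the
seconds range. Larger frames change nothing structurally — the
arithmetic is per-pixel.

## Known limitations

* The scalar-threshold subtraction makes intermediate detection ratios
  conservative (biased low) in proportion to `T/(A·D)`; absolute sRIN
  values near the detection limit understate integrity, while the
  endpoint levels (10 / 7.5 / 5 / 2.5) are exact.
* The misalignment statistic assumes flags are rare and independently
  placed under the null; heavy flagging (gross misregistration) violates
  this, but in that regime the fraction itself is the signal.
* The bulk proxy is linear in the per-probe survival probabilities and
  will not reproduce electrophoresis-RIN values for mixture samples.
* sRIN is an 18S-rRNA-based proxy; nothing here infers the integrity of
  specific mRNA species.
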