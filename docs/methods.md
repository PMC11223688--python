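# Methods

## Signal model and the motility amplitude

A pixel's magnitude time series S(t_i), i = 0..N−1, sampled at interval
`ts` over a span `ttotal = N·ts`, is treated as the sum of three processes
distinguished by their correlation time:

- **white noise**, decorrelating within one sample (shot noise and anything
  faster than `ts`);
- **motile scatterers**, decorrelating between `ts` and `ttotal`;
- **stationary scatterers**, effectively constant over `ttotal`, so that
  the long-lag autocorrelation approaches the squared mean signal S̄².

The unbiased discrete autocorrelation is
Γ(j·ts) = (1/(N−j)) Σ_i S((i+j)ts)·S(i·ts). The motility amplitude

    M = sqrt( (Γ(ts) − S̄²) / S̄² )

measures the share of the fluctuation that has survived one sampling
interval but will decay by the end of the record. The S̄² normalization
makes M unitless and invariant under uniform rescaling of the series, which
is what makes motility maps insensitive to depth-dependent signal roll-off.

**Negative radicands.** With finitely many samples, the estimate of Γ(ts)
can fall below S̄². The radicand is clamped to zero before the square root
and the event is flagged per pixel. Clamping (rather than, say, taking an
absolute value) means only positive excursions survive, which produces the
positive background floor of M over purely stationary scenes; the floor
grows with the noise level. A pixel whose mean signal is exactly zero
carries no motility information and is returned as NaN, never divided by.

## Sampling schemes and their estimators

All schedules are sets of 0-based retained slots on the nominal N-slot
grid; `ttotal = N·ts` is always derived, never stored independently.

- **FULL**: all N slots; Γ(ts) is the mean of all N−1 adjacent products.
- **UTS** (ratio r): slots {0, r, 2r, …}. The adjacent-product estimator is
  applied to the decimated series, whose spacing is r·ts — so it actually
  estimates Γ(r·ts). This low-biased quantity is reported deliberately:
  reproducing the decimation failure mode is part of validating the
  alternative.
- **NUTS** (ratio r): pairs (2kr, 2kr+1) for k = 0, 1, … while the second
  index fits in the record; a trailing slot that cannot complete a pair is
  dropped, never padded. Γ(ts) is the mean of the N′ pair products; S̄ is
  the mean of all retained samples. For N = 100 this gives N′ = 25/13/7/4
  pairs at r = 2/4/8/16 (closed form N′ = floor((N−2)/2r) + 1).

**r = 1 dispatch.** At r = 1 either scheme retains every slot. The NUTS
pair-product form would then use only the N/2 disjoint adjacent products —
half of the available information for no compression gain — so the lag-1
dispatcher and the imaging path route any r = 1 schedule to the full-series
estimator. `gamma_ts_nuts` itself evaluates the pair-product definition
faithfully at any r for callers who want it.

## Monte Carlo pixel model

S(t_i) = cn·fn(t_i) + cm·fm(t_i) + 1, with fn ~ N(0,1) i.i.d. and fm a
length-p moving average of i.i.d. N(0,1) draws scaled by sqrt(p) so that
Var[fm] = 1. The moving window uses N+p−1 fresh draws so every output point
is a full p-term average (no boundary truncation). Population moments:
Γ(0) = cn² + cm² + 1; the lag-j autocorrelation of fm is (p−j)/p, so
Γ(ts) ≈ cm²·(p−1)/p + 1; S̄ = 1. Hence mean M approximately recovers cm —
but sits measurably below it (e.g. ≈ 0.34 at cm = 0.40 with p = 20,
N = 100), because part of the motile signal decorrelates within one sample
and part persists past the end of the record, biasing Γ(ts) down and S̄²
up. Tests assert this under-recovery rather than exact equality. Noise is
purely additive (multiplicative noise omitted) and Gaussian; no physical
decorrelation model (diffusion/Lorentzian) is assumed.

Defaults mirror the spheroid study conditions: N = 100 samples, memory
p = 20 (memory time 20·ts), cn = 0.25, cm swept over [0, 0.5], 6000
replicate series per condition (about the pixel count of a typical
spheroid). The cm grid defaults to 11 evenly spaced points; the
through-origin slope is insensitive to grid density.

**RNG discipline.** Every replicate draws from an independent child stream
(`SeedSequence(seed, spawn_key=(replicate,))`) of the master seed, so a
compressed estimate sub-samples the *identical* series its uncompressed
partner used (paired comparison, mimicking sub-sampling one acquisition),
replicates are mutually independent, and a fixed seed makes every sweep
bit-reproducible. Sweep grid points derive independent sub-seeds (kept
below 2^31) from the master seed. The synthetic stack generator uses one
seeded generator per stack, vectorized over pixels along the time axis —
statistically identical to per-pixel streams and much faster; the
imaging-path-vs-simulator-path agreement is checked statistically in tests.

## Imaging conventions

Stacks are time-major (T × axial × lateral); the spatial mean-filter window
is specified (lateral, axial) with default 4 × 2 pixels, matching roughly
one resolution cell of the motivating instrument (≈ 12 μm × 3 μm). Edge
handling shrinks the window to its in-bounds intersection, so constant maps
stay exactly constant and no data are invented beyond the border; NaN
pixels are excluded from every window. Pixel-wise scatter analyses use the
filtered map; spheroid averages use the *unfiltered* map inside the
segmentation mask, with NaN pixels excluded. Segmentation itself is out of
scope — masks are inputs (8-bit label images, 0 = background).

## Fidelity and hypothesis-testing statistics

Compressed vs. uncompressed M scatter is summarized by the through-origin
least-squares slope m = Σxy/Σx² and Pearson's r (flagged, not zeroed, on
constant input; flagged low-n below 3 points). Dose/time condition tables
report mean, standard error and a two-tailed Welch (unequal-variance)
t-test against the pre-exposure baseline, computed in parallel per
compression method. p-values are raw — no multiple-testing correction, the
caller may apply one — and asterisk flags default to 0.05/0.01/0.001
(configurable). The key structural fact, exercised in tests: rescaling one
method's M column changes the regression slope but neither Pearson's r nor
any within-column t-test, which is why compression that merely shrinks M
leaves significance patterns intact.

The finite-population-correction variance of the pair-sampled Γ(ts)
(sampling without replacement) is noted but not implemented, as it is not
needed for any computed quantity here. White-noise floor subtraction from
Γ(0) is likewise out of scope: it requires instrument noise statistics and
an SNR estimate that magnitude stacks alone do not provide.

## What the synthetic data do and do not show

The synthetic stack generator places elliptical "spheroids" of elevated
motile weight over a stationary background with shared noise weight. It
reproduces the *temporal* statistics of the pixel model exactly, but not
properties of real OCT recordings: spatial speckle correlation between
neighboring pixels, depth-dependent SNR roll-off, bulk motion, or
non-Gaussian amplitude statistics. Passing tests therefore demonstrate that
the estimators and pipelines are correct for the stated model and that
compression fidelity behaves as designed; they do not certify performance
on any particular instrument's data. Published pixel-wise slopes and
correlations for real spheroid recordings (slopes ≈ 0.99–0.91, Pearson r
≈ 0.89–0.66 across compression ratios) require the original datasets and
are not recomputed here.

## Problem sizes and numerical choices

Test-suite simulations use 200–6000 replicates depending on the assertion's
tolerance; the acceptance script uses the full 6000 replicates per grid
point (a few seconds of CPU). The end-to-end cohort check uses two arms
(baseline cm = 0.40, suppressed cm = 0.20) of 8 synthetic spheroids on
30 × 30 scenes with N = 100 frames, analyzed uncompressed and pair-sampled
at r = 4 and r = 8 from the same stacks. Floating-point tolerances on
scale-invariance checks allow for square-root amplification of cancellation
error near a zero radicand (sqrt(eps) ≈ 1.5e-8). Monotonic tie-breaks,
empty regions, zero-mean pixels, oversized filter windows and mismatched
schedule/page counts are all rejected with explicit errors rather than
silently coerced.
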