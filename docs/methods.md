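# Methods

## Model and estimators

**Free diffusion.** All quantitative machinery assumes 2-D Brownian motion
at short time scales. For a trajectory sampled at interval `t_lag` the
time-averaged mean squared displacement at lag `n` is the mean of
`|r(i+n) − r(i)|²` over **all** overlapping frame pairs with frame
difference `n`. Pairing is by absolute frame difference, so trajectories
with dark (blink) gaps simply contribute fewer pairs at the affected lags;
no positions are ever interpolated. For a contiguous trajectory of `N`
frames the pair count at lag `n` is exactly `N − n`.

**Diffusion coefficient.** The first five lags (40–200 ms at 25 Hz) are
fitted to `MSD(n·t_lag) = 4·D₅·n·t_lag + c` by weighted least squares.
The weight of lag `n` is `1/σ²(n)` with `σ²(n) = s²(n)/n_pairs(n)`, the
variance of the per-lag MSD *estimate* (`s²` = sample variance of the
individual squared displacements). Weighting by the raw per-pair variance
instead is available via `weight_mode="sample_variance"`; with equal pair
counts the two give identical fits. The offset `c` absorbs static
localization error (`c = 4σ_loc²` for isotropic Gaussian noise of σ_loc
per axis; 25 nm noise ⇒ c ≈ 0.0025 µm²) and is not constrained to be
non-negative. Fitted `D₅` may be negative for noise-dominated tracks and
is reported as-is — truncation would bias every downstream population
summary; summaries instead carry the negative-D count.

*Known bias.* Because the weights are estimated from as few as
`N − 5` pairs, they correlate with the data, and for very short
trajectories (≈10 displacements) the weighted estimator's mean comes out
roughly 3% low (≈0.484 for a true 0.5 µm²/s). This is a property of
inverse-variance weighting itself, not of a particular implementation,
and disappears for the >50-step trajectories the pipeline actually
analyses. The validation suite asserts unbiasedness within two standard
errors at every grid length; the 10-step point sits right at that
boundary and can fail it.

**Degenerate fits.** If any fit lag has zero estimated variance (e.g. a
perfectly stationary track) the fit falls back to equal weights and is
flagged; a trajectory lacking two pairs at any fit lag is excluded and
logged rather than fitted.

## Linking

`link_detections` is deliberately simple — greedy nearest-neighbour
assignment frame to frame, gated at `max_disp` pixels per frame (default
2) and bridging up to `link_range` frames (default 5). It exists to close
the loop on synthetic data; experimental detections normally arrive
already linked by dedicated detection software, whose output the reader
consumes directly.

`relink_trajectories` closes blink gaps by coincidence in time and space:
fragment B continues fragment A when `0 < gap < 100` frames and the
squared end-to-start distance is below `0.1·gap` px². Fragments are
processed by ascending end frame and each takes its **earliest-starting**
eligible partner (ties by smaller distance²/gap). The earliest-partner
rule is a deliberate choice: a pure best-score rule prefers the *longest*
eligible gap for a near-immobile particle (the score's denominator grows
with gap while its noise-dominated numerator does not), bridging over —
and stranding — the fragments in between; with the earliest-partner rule
94–97% of true consecutive fragment pairs are recovered on ground-truthed
synthetic data, essentially every pair whose noisy separation satisfies
the spatial criterion. Merging iterates to a fixed point and is
idempotent. The >50-displacement length cut is applied after merging.

`remove_cross_channel_duplicates` deletes a trajectory seen in more than
one spectral channel when ≥80% of shared-frame positions lie within 1 px
(both thresholds configurable); the copy in the later-listed (lower
priority) channel is removed, and removals are logged.

All three stages only regroup localizations; the multiset of
`(frame, x, y)` values is conserved, and the test suite asserts it.

## Monte Carlo simulator

Steps are drawn as a uniform direction θ ∈ [0, 2π) and a Rayleigh length
via inverse CDF, `r = √(−4·D·t_lag·ln u)`, giving `E[r²] = 4·D·t_lag`
(0.08 µm² at the reference condition D = 0.5 µm²/s, t_lag = 40 ms).
Motion is boundary-free. The validation grid holds the total displacement
budget at 10,000 while trading trajectory count against length:
1000×10, 200×50, 100×100, 50×200, 20×500.

The multi-species generator adds, per particle: a diffusion coefficient
drawn from the species' mixture; i.i.d. Gaussian localization noise
(default σ_loc = 20 nm per axis, i.e. δr = σ√2 ≈ 28 nm, inside the
<30 nm precision of a good QD setup); and a two-state Markov blink
process (defaults: mean on-time 300 frames, mean off-time 20 frames,
chosen so fragment statistics land on the 200–600-step trajectory-length
scale of β-ME-stabilised QD data). Visible runs are emitted as separate
trajectories with a ground-truth table mapping fragments to particles.
An optional `max_blink_gap` truncates dark intervals, used to construct
relink test data whose gaps all fall below the 100-frame merge limit;
those scenarios also use near-immobile particles (D ≈ 0.0005 µm²/s),
matching the regime the coincidence criterion is designed for — for
mobile particles (D ≳ 0.01 µm²/s at this geometry) the expected squared
excursion 4·D·gap exceeds the 0.1·gap px² threshold and re-linking is
correctly refused.

What the generator does **not** emulate: raw images and PSFs, detection
failures, spectral crosstalk beyond simple duplication, confined or
directed motion, and state switching within a trajectory. Passing tests
therefore demonstrate the estimator and linking chain under ideal free
diffusion with realistic noise and blinking — not robustness to the full
heterogeneity of membrane data.

## Statistics

Two-sample K-S tests use the asymptotic p-value, except when both samples
have n ≤ 10, where the p-value is the exact permutation probability by
exhaustive enumeration of all C(n+m, n) relabelings (tie-safe statistic
evaluated on the pooled grid). At n = 100 per group the asymptotic route
realises a type-I error of ≈0.055 at α = 0.05. MAD is reported raw —
`median(|x − median(x)|)` without the 1.4826 Gaussian-consistency factor —
as the robust spread of a D₅ population; s.e.m. is `s/√n` and is reported
as 0 with a flag for single-observation populations. The
"significantly non-Gaussian" call on a population is implemented as a
Lilliefors-style Monte Carlo K-S against a normal with estimated
parameters, and is labelled as such. No multiple-testing correction is
applied across pairwise comparisons. Two-component population structure
is read off a fitted-D sample with an exact 1-D two-class
within-variance-minimising split (deterministic; appropriate only for
well-separated modes).

Percentage accuracy of a single-trajectory fit is
`%Difference = 100·|D_fit − D_sim|/D_sim`; the absolute value is forced
by the convention that accuracy summaries are positive while the fitted-D
population is itself unbiased. The pooled "average trajectory" analysis
fits the pair-count-weighted mean MSD over all trajectories; its quoted
uncertainty is the weighted-least-squares standard error of the slope
divided by 4.

## FCS sizing

Relative sizing uses `R_H = R_H(std)·D(std)/D(sample)` against the
Alexa488–IgG1 standard (5.6 ± 0.2 nm), valid when both measurements share
one buffer. Absolute conversion uses Stokes–Einstein with CODATA
`k_B = 1.380649×10⁻²³ J/K` and the reference buffer at 293 K,
η = 1.04 cP (5.6 nm ⇔ 36.85 µm²/s). Uncertainties propagate to first
order, relative errors adding in quadrature. The two routes agree
identically by construction, which the tests assert.

## Problem sizes and numerical choices

The validation grid (10,000 displacements per condition) runs in ~0.15 s;
test-suite replication uses 5–10 seeded replicates, and
`scripts/acceptance.py` averages 100 replicates per condition so reported
values estimate condition expectations with Monte Carlo error well below
the quantities' own spread. All randomness flows through
`numpy.random.default_rng` seeded explicitly; fixed seeds give
bit-identical outputs, including CLI runs (each writes a manifest with
its seed and parameters). Equal-length trajectory batches are fitted
through a vectorised path that the tests verify against the
per-trajectory route to 10 significant figures. CSV round-trips are
lossless: coordinates are written at full shortest-repr precision and
parsed with round-trip float precision.

## Limitations

- Only the free-diffusion model is fitted; anomalous exponents,
  confinement and transient states are out of scope.
- The frame-to-frame linker is greedy, not globally optimal, and is not
  meant to replace dedicated detection/linking software.
- The relinker's spatial criterion compares fragment end-to-start
  positions only, and is effectively specific to slow or immobile
  particles by design.
- The exact K-S enumeration is exponential in sample size and is capped
  at n = 10 per sample.
- FCS autocorrelation fitting is not implemented; the sizing module
  starts from already-fitted diffusion coefficients.
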