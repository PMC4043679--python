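# qdspt — multi-species quantum-dot single-particle tracking analysis

Quantum dots (QDs) are bright, photostable labels that make it possible to
track several membrane species at once — a lipid cluster, a GPI-anchored
protein, a transmembrane receptor — each in its own spectral channel, for
thousands of frames. The price is *blinking*: a QD intermittently goes
dark, so one particle's track arrives as many short fragments. `qdspt`
implements the analysis chain such an experiment needs, and the Monte
Carlo machinery to decide when single-trajectory analysis can be trusted:

- **Trajectory I/O** — MOSAIC Particle Tracker text output and a plain CSV
  dialect (`trajectory_id, frame, x, y, channel`), with explicit
  pixel/micrometer unit tracking (107 nm/pixel reference geometry).
- **Linking** — greedy frame-to-frame linking of detections, and a
  coincidence search in time and space that re-joins blink fragments: a
  gap of `g < 100` frames is closed when the squared end-to-start distance
  is below `0.1·g` px²; only tracks with more than 50 displacements are
  kept. Cross-channel duplicates (spectral bleed) are removed by
  shared-frame position coincidence.
- **MSD and diffusion fitting** — per-trajectory time-averaged MSD over
  all overlapping frame pairs, fitted at lags 1–5 (40–200 ms) to the free
  2-D diffusion model `MSD(n·t_lag) = 4·D₅·n·t_lag + c` by weighted least
  squares with inverse-variance weights; the offset `c ≈ 4σ_loc²` absorbs
  static localization error.
- **Monte Carlo validation** — Rayleigh-step Brownian simulation
  (θ ~ U[0,2π), r = √(−4·D·t_lag·ln u)) on a constant 10,000-displacement
  budget, quantifying accuracy (mean %Difference = 100·|D_fit − D_sim|/D_sim)
  and precision (its s.t.d.) as a function of trajectory length, against
  the pooled average-trajectory fit.
- **Population statistics** — mean ± s.e.m. and (unscaled) MAD summaries,
  empirical CDFs, and pairwise two-sample Kolmogorov–Smirnov tests
  (asymptotic p-values; exhaustive permutation enumeration when both
  n ≤ 10).
- **FCS-based probe sizing** — hydrodynamic radius from solution diffusion
  coefficients, relative to an IgG1 standard (R_H = 5.6 ± 0.2 nm) or
  absolutely via Stokes–Einstein (D = k_B·T / 6πηR_H).

The synthetic-data generator (`qdspt.simulate`) produces multi-channel
QD-like datasets — per-species diffusion mixtures, Gaussian localization
noise, two-state Markov blinking — with ground truth, so every pipeline
stage is testable end to end.

## Worked example

How accurately can D be read off a *single* trajectory?

```python
>>> from qdspt import run_validation
>>> print(run_validation(seed=0).to_wide_text())
Monte Carlo validation (D_sim=0.5 um^2/s, t_lag=40 ms)

Condition (trajectories x steps):  1000x10  200x50  100x100  50x200  20x500
-- Single trajectory analysis --
D_fitted mean+/-s.t.d. [um^2/s]:   0.473+/-0.339  0.496+/-0.138  0.509+/-0.101  0.494+/-0.069  0.504+/-0.028
%Difference mean+/-s.t.d.:         52.7+/-43.0  22.1+/-16.6  16.2+/-12.1  10.8+/-8.4  4.5+/-3.3
-- Average trajectory analysis --
pooled D +/- a.s.e. [um^2/s]:      0.496+/-0.005  0.499+/-0.004  0.511+/-0.004  0.495+/-0.004  0.505+/-0.004
pooled %Difference:                0.72  0.17  2.13  0.93  0.95
```

Reading: with only 10 displacements per trajectory the single-trajectory
estimate is off by ~53% on average — useless individually, although
pooling all 10,000 displacements still recovers D to better than 1%. At
50 displacements the error is ~22%, at 200 it is ~11%, at 500 ~5%. That
ladder is why the pipeline only fits trajectories longer than 50 steps.

The numbered drivers under `analysis/` run the full story:
`01_validate_trajectory_length.py` (the grid above, replicated),
`02_multispecies_pipeline.py` (three-species synthetic experiment through
dedupe → relink → fit), `03_population_comparison.py` (K-S tests and
MAD/mean treatment effects), `04_fcs_sizing.py` (probe sizing). Each
writes its tables under `results/`.

A `qdspt` console command exposes the same stages
(`simulate`, `link`, `relink`, `dedupe`, `msd`, `fit`, `validate`,
`compare`, `fcs-size`, `run`); see `qdspt --help`.

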