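# Methods

## Nonselective pulse model

A punctum is one state variable `A` (aggregated ATG13, arbitrary units):

    dA/dt = kprodATG13 * A^m * w_acc  -  kremATG13 * A^r * w_rem

`m ≥ 0` is the partial reaction order of accumulation on the already
aggregated complex; removal is first order by default (`r = 1`), with the
alternative reading `r = m` selectable via `removal_order_m` so the
cooperativity hypothesis can be tested in both directions. `w_acc`/`w_rem`
equal the wortmannin factor `kwrtm ∈ (0, 1]` when wortmannin is active and
the variant targets that reaction, else 1. Event variants 1–3 run pure
accumulation on `[0, t)` and pure removal on `[t, ∞)` (hard switch);
eventless variants 4–6 run both terms throughout. `A(0) = atg13_seed`
(default 0.01 AU) must be positive because the `A^m` feedback stalls at
exactly zero; it is a nuisance constant far below observed peaks and can
optionally be fitted (`fit_seed`).

**Integration.** Every variant is piecewise separable: power-law growth
`dA/dt = cA^m`, power-law decay, and (for eventless, first-order removal)
the substitution `u = A^(1-m)` giving a linear ODE. The default integrator
therefore evaluates the exact closed-form solution, which is what the
multi-start budgets require (~10^5–10^6 objective evaluations per fit); an
adaptive LSODA route that splits the trajectory exactly at the event time
is kept and cross-checked against the analytic route to ~1e-9 relative in
the tests. Finite-time blow-up (possible for `m > 1`) raises
`IntegrationError`; objectives translate it to `+inf`.

## Hybrid mitophagy model

Cycle `k = 1, 2, …` of one engulfment event:

1. sample time-to-peak `t_k ~ Normal(t_mean, t_sd)` truncated > 0;
2. ATG13 accumulates for `t_k`, then is removed until `A < 1.05 * seed`
   (the trough criterion is a package constant; the source data define no
   trough rule);
3. cumulative LC3 grows at `kprodLC3 * A` while the cycle runs
   (cycle-coupled production; LC3 is flat in the inter-cycle gaps);
4. after a programmed delay `kpeak * k^p` the model evaluates — reading
   LC3 with a lag `Tau`, default 0 — whether cumulative LC3 has reached
   `engulf_coeff * MT_diam`; if so the event terminates, otherwise the
   next aggregation starts.

`MT_diam ~ Normal(mt_diam_mean, mt_diam_sd)` truncated > 0 is drawn once
per event. The engulfment threshold is linear in diameter, matching the
predicted and observed linear count–diameter relation; an area-based
(quadratic) threshold would be a one-line change in the termination test.
Termination is guaranteed for `kprodLC3 > 0` because every cycle adds a
positive LC3 increment; `kprodLC3 = 0` (or `kremATG13 = 0`) raises
`EngulfmentError`. All randomness flows through one seeded generator;
identical seeds give bit-identical results, and populations spawn
independent child streams per event.

Observables mirror the imaging cadence: traces are emitted on a 10 s grid,
with internal fine-grid (1 s) evaluation of each cycle and trapezoidal LC3
integration; inter-cycle gaps are represented by their endpoints (both
signals are constant there under linear interpolation).

### Default parameters

Published fits: `kprodATG13 = 0.0082`, `kremATG13 = 0.0029`, `m = 1.01365`
(nonselective); `kprodATG13 = kremATG13 = 0.0114`, `p = 2.79` (mitophagy).
Everything else is not published and is a package choice, fixed once from
the model structure so that simulations reproduce the qualitative study
picture — a mean event of ~6–7 aggregation cycles terminating near the
910 s analysis endpoint, peak counts spanning several values across a
population:

| parameter | default | role |
|---|---|---|
| `kwrtm` | 0.5 | wortmannin down-regulation factor |
| `t` (nonselective) | 200 s | event time; population spread 40 s (Normal) |
| wortmannin peak times | LogNormal(ln 120, 0.8) | right-skewed, detectably log-normal at n = 35 |
| `t_mean`, `t_sd` (mitophagy) | 45 s, 9 s | per-cycle time-to-peak |
| `kpeak`, `Tau` | 0.7 s, 0 s | delay law base; LC3 read lag |
| `kprodLC3`, `engulf_coeff` | 0.1 s⁻¹, 0.65 AU/µm | only their ratio × diameter is identifiable |
| `mt_diam_mean`, `mt_diam_sd` | 1.0 µm, 0.3 µm | fragment diameters |
| noise | 5% multiplicative lognormal | fluorescence-like |
| bleach | exp decline, τ = 600 s | slow acquisition decline |

## Trace pipeline

Order is fixed: spline-smooth → iterative integer-frame alignment against
the population mean → restore original values at the aligned positions →
drop irregular traces → trim to ≥3 repeats per frame → regularize.
Details:

* **Smoothing.** A least-squares cubic spline with ~n/5 degrees of freedom
  supports alignment and irregularity screening. For peak *localization*
  this is too stiff (it displaces peaks of ~90 s oscillations), so peak
  positions are always taken from a light Savitzky–Golay filter (window 7,
  order 2) with parabolic sub-frame refinement of each extremum.
* **Alignment.** Each trace takes the integer-frame shift (±5 frames)
  maximizing its correlation with the current population mean, iterated to
  convergence; the cumulative shift is capped (beyond the cap a
  quasi-periodic trace has latched onto the wrong cycle) and the common
  mode (median shift) is removed every sweep.
* **Irregularity.** A trace is dropped when it has no detectable peak, its
  inter-peak delay CV exceeds 1.5, or >20% of frames are missing — a
  reproducible surrogate for the study's manual removal of irregular
  recordings.
* **Regularization.** A decaying exponential fitted to the trough envelope
  is divided out; declines below 10% over the trace are left alone (that
  is envelope structure, not bleaching). Failures warn and return the
  input unchanged.
* **Peak trains.** `find_peaks` with prominence ≥ 10% of range and ≥ 2
  frames separation; one trough precedes each peak; trough→peak rise times
  give the empirical `t_mean`/`t_sd` feeding the mitophagy model.

## Distribution analysis

Shapiro–Wilk on the raw sample decides normality at α = 0.05; if rejected,
Shapiro–Wilk on the log sample decides log-normality (the argument order
of the study); otherwise "neither". Moments are bias-corrected G1/G2; the
population (uncorrected) forms are available. Q–Q points use plotting
positions `(i-0.5)/n` against moment-fitted references. A QC gate warns if
peak times correlate with initial intensities (misidentified aggregation
starts).

## Estimation

* **Objective.** Unweighted SSR over all time points of all conditions.
  Peak-synchronized data are placed on the simulation axis by one common
  offset (earliest frame at 0); a condition labeled "wortmannin" is
  simulated with the factor active.
* **Multi-start.** `n_starts` independently seeded differential-evolution
  runs (rate-like parameters in log10 space; bounds: rates 1e-6–10,
  m 0–4, kwrtm 1e-3–1, t 10–600 s, p 0–6), best 75% retained, desk-scale
  default 50 starts with 120 iterations × population multiplier 15. The
  protocol-scale configuration (1000 starts, 1000 iterations, swarm 100)
  is reachable through `optimizer_cfg`.
* **AIC.** Gaussian-residual form `n ln(SSR/n) + 2k`; only differences
  between variants fitted to the same data are meaningful.
* **Profile likelihood.** One parameter is scanned over its bounds
  (41 points; log-spaced for rates), all others re-optimized by
  warm-started Nelder–Mead marching outward from the best fit. The CI at
  level α collects the connected region where the profile stays below
  `SSR_min * exp(χ²₁(α)/n)`; an end at the bound is flagged open
  (non-identifiable on that side).

### Two-stage mitophagy calibration

**Stage 1** estimates `(kprodATG13, kremATG13)` from the first
aggregations, synchronized on their denoised peak. Each first-peak segment
is cut at the first sustained post-peak upturn of the smoothed curve and
fitted *jointly* against a pulse with its own observed rise duration, in
log space (matching multiplicative noise), with the model clipped at the
resting seed level and each trace's argmax frame excluded (a noise-selected
order statistic). Fitting the *averaged* pulse instead is measurably biased:
alignment at the argmax frame smears the kink and the amplitude–coverage
correlation distorts the late decay. Segments whose observed rise is more
than 3 standard deviations from the rise-time mean are screened out (a
missed first peak, not kinetics).

**Stage 2** fixes `t` and `MT_diam` at their empirical means and fits the
oscillation parameters on the full mean time course in two rounds: round 1
estimates `(kprodLC3, kpeak, p)`; round 2 fixes `kprodLC3` (its optimum
lies on a plateau — only `kprodLC3 × engulfment duration` is identified,
the documented non-identifiability) and re-estimates the interdependent
`kpeak`. The objective combines the raw-trace SSR with a peak-position
term (sub-frame detected positions, 3 s scale), a peak-count penalty and a
non-termination penalty, warm-started from a log-log regression of the
observed inter-peak delays. The position term removes a ridge-regularized
affine drift (offset sd 3 s, slope sd 2 s/cycle) before scoring: a
few-percent error in the stage-1 rates shifts every cycle's active
duration, which accumulates linearly in the peak positions and would
otherwise leak into the delay exponent; genuine delay growth is convex in
the cycle index and passes through the prior. At true kinetics the
estimator is unbiased (zero-noise recovery `p = 2.784` vs 2.79).

## What the synthetic data do and do not show

The generators emulate single-pulse populations (Normal / LogNormal peak
times, wortmannin-reduced amplitude), stochastic oscillatory events,
drifting "irregular" traces for the filter, and diameter measurement
tables — with multiplicative lognormal noise and a shared exponential
bleach. They do **not** emulate segmentation/tracking artifacts, frame
drops, heteroscedastic backgrounds, cell-to-cell expression differences,
or any spatial structure. Passing recovery tests therefore demonstrates
the correctness and calibration of the estimation machinery under the
model's own assumptions, not performance on raw microscopy data. Two
consequences observed in practice: the mean of *stochastic* oscillatory
traces desynchronizes after a few cycles, so a stage-2 fit to such a mean
(the `fit-mitophagy` CLI convenience path) degrades for late cycles — the
calibration protocol instead uses the deterministic mean course, as in the
original two-stage design; and population-mean refits of peak-synchronized
pulses with heterogeneous event times carry an effective initial amount
larger than the single-trace seed (the seed can be co-fitted for that use).

## Numerical choices and degenerate inputs

Ties in peak synchronization break to the earliest frame. Normal draws for
times and diameters are truncated at zero by resampling. Constant samples,
flat traces, fewer than 3 observations, zero-variance correlations and
sub-3-frame windows raise `ValueError` with specific messages. The
retained multi-start subset is `max(1, floor(0.75 n))` so the best start
is always retained. Integration failures inside objectives penalize with
`+inf` rather than raising. `delay_for_cycle` rejects cycle indices < 1.

## Known limitations

* `p` and `kpeak` lie on a pronounced ridge at 10 s sampling; recovery of
  `p` to ~5–10% requires the drift-regularized position term and is
  limited by first-peak kinetic precision.
* `kprodLC3` is reported but only its product with the engulfment budget
  is identified (open profile on one side).
* The irregularity criterion and the trough/upturn rules are reproducible
  surrogates for manual curation; on real data their thresholds would need
  revisiting.
* The ±5% one-at-a-time robustness probe of the fitted model is
  qualitative (shape preservation), not an asserted bound.
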