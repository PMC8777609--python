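# Methods

## Burden metrics

A surgery is a MAP record sampled nominally every 20 s (the update cadence of
waveform-derived MAP on advanced hemodynamic monitors); between samples the
trace is treated as piecewise linear.  Hypotension is *strictly* below the
threshold (default 65 mmHg): a sample exactly at 65 mmHg is not hypotensive.
Threshold crossings are located exactly on the linear segments, which makes
episode counts, times and areas invariant under grid refinement — a property
the test suite asserts.

Two area conventions appear in the clinical literature and both are
implemented: the true integral of the depth below threshold (`trapezoid`, the
default) and the product of the worst depth with the total time below
threshold (`maxdepth_x_time`).  They coincide exactly when every episode has
constant depth (the textbook five-episode example); for any other trace the
trapezoid area is a lower bound.  The time-weighted average (TWA) is always
area divided by total surgery duration, so the identity
`twa * duration == area` holds to float precision in every summary.

Episode debouncing is off by default (`min_duration = merge_gap = 0`), since
a 20 s cadence already suppresses sub-sample noise; both knobs exist because
monitors differ in how they bridge short artifact gaps.  When episodes are
merged across a gap the gap counts as episode time; summaries are always
computed over the *retained* episodes so that "no episodes" implies zero
time, zero area and zero TWA regardless of configuration.

## Nonparametric statistics

All two-arm comparisons are rank-based, matching how small hypotension trials
are analyzed:

* **Mann-Whitney U** — midranks for ties; exact p from the
  dynamic-programming null distribution of U when `n_x * n_y <= 400` and the
  pooled data are tie-free, otherwise the tie-corrected normal approximation
  with continuity correction.  The exact path agrees with full enumeration
  (tested to 8 + 8) and with independent implementations to 1e-12; exact and
  approximate p differ by < 0.02 at 20 + 20.
* **Hodges-Lehmann** — point estimate is the median of all pairwise
  between-group differences; the CI takes order statistics of the sorted
  differences at the critical ranks of the Mann-Whitney null (exact ranks up
  to `n_x * n_y <= 2500`, normal approximation beyond).  Discreteness is
  resolved conservatively: the largest rank whose null probability stays
  within α/2 is used, so achieved coverage is at least nominal up to rank
  granularity (measured 94.2% at 20 + 20 for a nominal 95%).  The estimator
  is validated against R's `wilcox.test(conf.int=TRUE)`.
* **Spearman** — Pearson correlation of midranks, p from the t
  approximation with n − 2 df.  Correlation matrices report a cell as
  unavailable (NaN) when fewer than 3 complete pairs exist or a vector is
  constant; nothing is imputed.
* **Chi-square** — Pearson statistic without continuity correction,
  df = (R−1)(C−1).
* **Normality** — KS distance to a normal with estimated mean/SD.  Because
  parameters are estimated, classical KS tables are invalid; the p-value is
  simulated (add-one Monte-Carlo, default 2000 replicates, seeded).
* Degenerate comparisons where *all* pooled values are identical return
  p = 1 (no evidence) rather than an error, so that identical arms yield a
  zero difference instead of a crash.

No multiple-testing correction is applied: each p-value is reported
marginally, mirroring how pilot-trial tables are presented.  This is a
documented limitation, not an endorsement — with 8 analytes and 4 burden
outcomes, family-wise error is substantial.  Published tables of this design
occasionally contain internally inconsistent entries (a CI excluding zero
beside a non-significant p, or a sign at odds with neighbouring rows); this
package always reports the statistics it computes, so such inconsistencies
are not reproducible here by construction.

## Decision policies

The proactive policy fires only when the HPI alert score is strictly above
85%, after an artifact check (a flagged artifact yields "observe").  The
branch logic — SVV > 13% ⇒ fluid; else Eadyn < 0.8 ⇒ vasopressor; else
dP/dt_max < 480 mmHg/s ⇒ inotrope; else observe — follows common hemodynamic
practice for preload responsiveness, arterial tone and contractility.  These
branch thresholds are package conventions (configurable in `RuleConfig`), not
values prescribed by any specific device or protocol.  The reactive policy
applies the same branches but triggers only once MAP is strictly below
65 mmHg.  The rule table is exhaustive and mutually exclusive; the
"combination" action is reserved for user configurations that fire multiple
branches.

## The generator

The generator emulates the *statistical* structure of a two-arm
early-warning-system trial, not cardiovascular physiology:

* **Durations** are log-normal with medians 207 min (intervention) and
  237 min (control) and log-sigmas 0.228 / 0.374 backed out of the reported
  interquartile ranges of such surgeries.
* **Baseline MAP** is a mean-reverting AR(1) (sampled Ornstein-Uhlenbeck)
  around 78 mmHg with stationary SD 2 mmHg and a 5-min time constant — high
  enough that noise alone essentially never crosses 65 mmHg, so every episode
  is event-driven.
* **Hypotensive events** arrive as a Poisson process over the surgery minus a
  5-min margin at each end, with a per-patient gamma frailty (shape 1) that
  over-disperses episode counts the way real cohorts are over-dispersed: most
  affected patients have a handful of episodes, a few have many.  Each event
  is a trapezoidal dip (90 s ramps, log-normal hold ≥ 60 s, nadir drawn
  uniformly in 52–62 mmHg).
* **Protocols.**  Control events are treated reactively at the threshold
  crossing (hold capped at 180 s — shortened, never averted).  Intervention
  events are alerted with probability 0.85 about 5 min before full depth; an
  alerted event is fully averted with probability `treatment_efficacy`
  (residual dip bottoms out 8 mmHg above threshold), otherwise truncated
  (hold scaled by 0.6 after capping).  Every alert and policy call is written
  to the event log.
* **Calibration.**  With gamma frailty the incidence
  P(≥1 episode) = 1 − E_T[(1 + λqW(T)/k)^(−k)] is available in closed form up
  to a quadrature over the duration distribution (W = exposed hours, q = 1 for
  control, q = 1 − sensitivity × efficacy for intervention).
  `calibrate_event_rate` and `calibrate_treatment_efficacy` invert this by
  root-finding; the frozen defaults (event rate 1.1096/h, efficacy 0.9796)
  reproduce the 80% / 38% design incidences, which simulation confirms to
  within sampling error.  The implied overall aversion probability,
  0.85 × 0.98 ≈ 0.83, is what an alert system with ~85% sensitivity and a
  reliably executed protocol would deliver.
* **Biomarkers.**  T0 panels are log-normal around plausible assay medians.
  Deltas are `slope * asinh(metric / scale) + noise`; the asinh compresses
  the heavy right tail of burden metrics so one slope spans zero-burden and
  high-burden patients.  S100B is keyed to episode count and NGAL to TWA,
  with slopes and noise calibrated so the pooled Spearman correlations center
  near 0.584 and 0.316 at trial scale; NSE rises with absolute hypotension
  time and glutathione (GSH) falls with TWA, giving the intervention arm
  lower NSE and higher GSH deltas through its lower burden alone.  The other
  four analytes carry no injected dependence.  Negative generated
  concentrations are truncated at zero (logged).

What the generator does **not** emulate: cardiac output and its regulation,
drug pharmacokinetics, anesthetic depth, surgical stimuli, measurement
artifacts, or the joint distribution of burden *shape* (depth vs duration
trade-offs) in real patients.  Passing tests therefore demonstrate that the
analysis pipeline is correct and well calibrated under a realistic data
*shape* — zero-inflated, right-skewed burden; over-dispersed counts; rank
correlations of the stated size — not that any physiological claim holds.

## Power

The design claim — 20 patients per arm give 80% power to detect an incidence
drop from 80% to 38% at two-sided α = 0.05 — is reproduced by Monte-Carlo:
each replicate draws 20 Bernoulli outcomes per arm and applies a two-sided
two-proportion z-test.  The *pooled-variance* (score) z-test is the default
because it is the test underlying the classical sample-size formula, which
yields n = 20.3 per arm at 80% power for exactly these inputs; its exact
power at n = 20 (computed by 21 × 21 binomial enumeration) is 0.791, and its
exact size 0.043.  The unpooled Wald variant (exact power 0.850, size 0.081 —
anticonservative at this n) and a Welch t-test on the 0/1 encodings are
available by flag.

## Randomization

Permuted blocks drawn from sizes {4, 6}: at each step a block size is chosen
uniformly among those that keep the remaining total composable, and each
block is internally balanced 1:1 and shuffled.  Final arm totals are exactly
equal for every seed, and no assignment prefix can diverge by more than half
the largest block.  `simulate_trial` falls back to a single balanced block
(with a warning) when the configured sizes cannot compose a tiny requested
trial, so degenerate configurations still run.

## Reproducibility and numerics

One master seed governs a run; per-patient generators are derived through
`SeedSequence([seed, stream, index])` so any patient can be regenerated in
isolation and whole trials are bit-identical across runs.  Burden geometry is
exact on the piecewise-linear trace (crossings by linear interpolation,
trapezoid integration over episode intervals); float seams between adjacent
sub-threshold segments are merged at 1e-12 s.  The near-rectangular worked
example uses 1 µs ramps anchored at the threshold, making the below-threshold
time exact and the area exact to ~4e-7 mmHg·min.

The acceptance script uses 20,000 Monte-Carlo replicates for power and
10,000 simulated patients per arm for the incidence checks — sizes at which
binomial sampling error (≤ 0.5 percentage points) is well inside the
calibration tolerances; the whole script completes in well under a minute.

## Known limitations

* The generator's event shapes (trapezoidal dips, uniform nadirs) are
  conventions chosen for tunability; real burden distributions are only
  matched in their summary behaviour, not their fine structure.
* The Hodges-Lehmann CI is discrete; at very small samples (n_x·n_y below
  ~40) the nominal 95% level may be unattainable and the full range of
  pairwise differences is returned.
* The Monte-Carlo normality p-value has simulation error ~1/√reps; raise
  `reps` for borderline decisions.
* Biomarker correlations are injected via a single monotone link per
  analyte; real panels have inter-analyte correlation beyond what burden
  induces, which is not modelled.
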