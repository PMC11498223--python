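# Methods

## The kinetic model

Cell mass grows as dM/dt = γ·M^δ with δ = 0.8, a mild departure from pure
exponential growth. Rb synthesis is proportional to the instantaneous
growth rate, and degradation is first order with a cell-cycle-dependent
rate:

    dRb/dt = α·M^δ − β(t)·Rb,       c = Rb/M.

In the **degradation-step** variant β(t) = β₀ through G1 and ε·β₀ through
S-G2-M. β₀ = ln2/6.4 h⁻¹ is pinned to the measured early-G1 half-life and
ε = 0.2 encodes the measured 80% drop in degradation rate after the G1-S
transition. In the **synthesis-step** variant β is constant at β₀ and α is
instead multiplied by 1.2 in S-G2-M; this is the alternative hypothesis
that a modest synthesis up-regulation, rather than stabilisation, drives
the concentration recovery.

The G1-S transition fires when c crosses `conc_threshold` *downward*:
falling Rb concentration is what releases E2F, so dilution below the
threshold is the biologically meaningful direction. S-G2-M is a fixed
timer (t_sg2m = 12 h), after which division halves M and Rb symmetrically —
the rule that keeps concentration exactly continuous across division and
is required for birth-aligned concentration traces.

### Parameters

| symbol | meaning | default | units | origin |
|---|---|---|---|---|
| β₀ | G1 degradation rate | ln2/6.4 ≈ 0.1083 | 1/h | measured half-life |
| ε | S-G2-M step factor | 0.2 | – | measured 80% step |
| δ | growth-law exponent | 0.8 | – | sub-exponential growth |
| γ | growth constant | 0.03717 | h⁻¹·(unit mass)^0.2 | ~20 h doubling at unit mass |
| α | effective synthesis rate | 0.1 | a.u./h | sets the Rb scale only |
| conc_threshold | G1-S trigger | 0.744434 (degradation) / 0.637849 (synthesis) | a.u. | calibrated, see below |
| t_sg2m | S-G2-M timer | 12 | h | typical S-G2-M duration |
| dt | Euler step | 0.01 | h | convergence-checked |

Only β₀ and ε are measured quantities; γ, δ, α, the threshold and the timer
are a one-time calibration chosen so the limit cycle has a ~10 h G1 and a
~22 h cycle. The thresholds were found by bisection on limit-cycle G1
length and frozen. α is a pure scale: it multiplies Rb and the threshold
together and cannot change the dynamics' shape.

### Numerics

Integration is explicit Euler. The two phase events are located inside the
step — the threshold crossing by linear interpolation of the concentration,
the timer expiry by truncating the step exactly — and the step grid
re-aligns at each event. Without this the event times are quantised to the
dt grid and the cycle-to-cycle map inherits ~1e-4 alignment jitter, which
would make tight burn-in tolerances meaningless. With it, burn-in
(successive cycles' birth concentration and length changing by < 1e-6
relative, cap 200 cycles) converges geometrically in ~35 cycles, halving dt
moves the birth concentration by < 3e-5 relative, and two arbitrary initial
conditions agree to ~1e-6. If the threshold is unreachable the run is
flagged arrested rather than raising.

Decay mode (synthesis off, phase pinned — the in-silico analogue of an
induction-withdrawal experiment) is a constant-coefficient linear ODE, so
the amount series uses its closed form exp(−β·t) directly; an Euler version
would carry a ~5e-4 relative rate bias into the recovered β for no benefit.

On the reference limit cycle the Rb amount changes by ~8% over the first
half of G1 (synthesis nearly balances degradation — the "dilution"
phenomenology) and the concentration amplitude is ~0.41; the 1.2×
synthesis-step variant reaches only ~0.08.

## Synthetic cohorts

The generator emulates the statistical structure of the live-imaging
experiments, not images: nuclei are already segmented and tracked, and each
cell is one row per 20-minute frame over a 48-hour movie.

**Half-life heterogeneity.** Published per-cell half-life distributions are
summarised as a median with an asymmetric central-75% range, which a plain
log-normal cannot match. Cohorts therefore draw half-lives from a
*two-piece log-normal*: log-deviations below/above the median have separate
scales σ_low = ln(median/q_low)/z and σ_high = ln(q_high/median)/z, with
z = Φ⁻¹(0.875). Calibration to (median, q_low, q_high) is exact by
construction; the reference WT condition uses 6.4 (5.3–9.4) h for early G1
and 37.3 (29.2–45.4) h for S-G2, and the UBR5-knockout condition doubles
the early-G1 median at unchanged shape. The "75% range" is read as the
central 75% interval (12.5th–87.5th percentiles), distinct from the
quartile boxes of the published box plots.

**Measurement model.** Channels carry multiplicative i.i.d. log-normal
noise per frame (mean one, CV 0.05 by default — a typical fluorescence
noise floor; the source experiments do not state one) plus additive
background of 10 a.u./pixel × nuclear area. Nuclear area starts near
400 px² (10% CV across cells) and grows exponentially at 0.021/h so the
area^{3/2} volume proxy doubles over ~22 h.

**Decay cohorts.** Each cell has a fixed phase; its reporter decays as
I₀·exp(−kt) with k = ln2/t_half. The Geminin channel is on for the whole
movie iff the cell is S-G2, plus a small constitutive basal level (500
a.u.) in G1 cells — without a basal level the background-corrected "off"
state is exactly zero and a data-derived positivity threshold degenerates.

**Cycling cohorts.** Births are staggered uniformly over the first half of
the movie (late-born cells contribute too few frames to any estimator).
Ground-truth concentration declines exponentially through G1 at 0.0315/h
(amount constant while volume grows) and recovers through S-G2-M to the
birth value at division; traces follow one cycle, lineages are out of
scope. G1 length is drawn from a 10 (7–14) h two-piece log-normal,
optionally scaled by (birth concentration/median)^1 to build in the
positive dependence the correlation statistics are tested against, or
generated as a constant-rate exit process (0.1/h) for the null cohort. The
HDHB-type cytoplasm/nucleus ratio is 0.5 + 1.0·logistic((t − t_infl)/1 h)
with inflection offsets of 8 (6–11) h after birth; the sensor's true
kinetics are not published, so these are deliberately simple defaults,
exposed in the config.

What passing tests on these cohorts shows: the estimators recover the
generating parameters under the stated noise model and detect built-in
dependences with correct sign. What they cannot show: robustness to
segmentation/tracking errors, photobleaching, focus drift, cell death, or
mis-specified noise — none of which the generator emulates.

## Estimators

**Concentration.** corrected = raw − median background × area, floored at
zero with the floored-frame count kept (concentrations are physically
non-negative; the flag preserves auditability); concentration =
corrected/area^{3/2}.

**Phase annotation.** Frames with background-corrected Geminin above a
threshold are S-G2; the maximal Geminin-negative run from birth is G1 and
qualifies as early G1 iff longer than 7 h. The default threshold is 3× the
median of the *pooled* lowest quartile of corrected Geminin values across
the cohort. A per-cell baseline was considered and rejected: a cell that is
Geminin-positive for its entire trace has an "on"-level baseline and would
never cross 3× its own quartile, so whole-movie S-G2 cells (the decay
experiment's S-G2 arm) would be mislabelled G1. Any explicit threshold can
be passed instead.

**Half-life fits.** Ordinary least squares of ln(intensity) on time. Under
multiplicative log-normal noise this is the maximum-likelihood estimator
(verified against a brute-force grid search); it is also scale-invariant,
and a nonlinear fit on raw values would weight early bright frames
arbitrarily. Fits start 12 h after withdrawal (3 h for fast-degrading
variants) to exclude synthesis from residual mRNA, require ≥ 10 frames, and
drop non-positive values with a logged count. Slopes at or below round-off
scale (k ≤ 1e-12/h) are reported as non-degrading (t₁/₂ = ∞); such cells
are excluded from distribution quantiles and reported as a flagged
fraction. Cohort summaries use linear-interpolation percentiles; condition
comparisons use the ratio of medians with a seeded 2000-rep percentile
bootstrap over cells.

**Cdk activation.** A 4-parameter logistic (baseline, amplitude, midpoint,
timescale) is fitted to the ratio trace; the midpoint is the activation
time, accepted when the amplitude exceeds 3× the residual RMS and the
midpoint lies inside the observed window. A logistic fit was chosen over a
numerical second derivative because 20-minute sampling makes pointwise
curvature estimates noise-dominated. Cells with no accepted inflection are
Cdk-low — the classification's definition ("activates later") covers
late-or-never activation. The 5 h threshold is the published rule.

**G1-S transition hazard.** Person-time estimation: every G1 frame
contributes its frame interval of risk time to the concentration bin it
occupies; an observed G1→S transition is an event in the bin of the last
G1 frame; rate = events/risk time. The association statistic is a
risk-time-weighted rank correlation across bins with a t-approximation at
the effective sample size (Σw)²/Σw²; only its sign and rough significance
are interpreted, since the underlying publication defines no operational
"transition rate" estimator. On constant-hazard simulations the estimator
is unbiased (mean over 100 replicates within 5% of the configured rate).

## Problem sizes

Reference analyses use 200 cells per phase/condition and 200-cell cycling
cohorts — comparable to the published per-condition cell counts and large
enough that the median half-life's sampling error (~2%) sits well inside
the 5% recovery tolerance. The Monte-Carlo quantile checks use 10⁶ draws.

## Known limitations

* No image-level effects (segmentation error, bleaching, drift) and no
  lineage structure beyond one division.
* The model has no stochasticity and no explicit phosphorylation state;
  the degradation step stands in for the phosphorylation switch, assumed
  coincident with the threshold crossing.
* γ, δ, α, threshold and timer are calibration choices, not measured
  values; conclusions drawn from the model are qualitative (shape,
  sufficiency/insufficiency of variants), with only β₀ and ε quantitative.
* The ε-sensitivity of G1 length is threshold-mediated: raising ε (weaker
  S-G2-M stabilisation) lowers the birth concentration and *shortens* G1 at
  a fixed threshold, up to the point where the threshold becomes
  unreachable and the model arrests.
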