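# Methods

This note documents the models, estimators and design choices behind the
package, and what the synthetic-data tests do and do not establish.

## State estimation

Tracks are sampled at 175 Hz in a platform-centred frame (`y` normal to the
landing surface, positive into the arena). Positions are low-pass filtered
with a second-order Butterworth filter applied forward and backward
(zero-phase; cut-off 20 Hz, reflective edge padding of three filter orders),
time is shifted so `t = 0` at the closest approach (ties broken to the
latest minimum, since the final approach terminates the manoeuvre), and
derivatives use second-order central differences with one-sided second-order
stencils at the ends. The approach acceleration is differentiated from `V`
rather than taken as a second difference of `y` so that `V` and `A` are
mutually consistent. Samples with `y ≤ 5 mm` are dropped: `r = V/y`
diverges at contact and every analysed segment lives away from it.
Segmentation consumes only the final approach — the last contiguous stretch
of positive approach speed ending at touchdown, with the sign test taken on
a 5 Hz-smoothed copy of `V` so that tracking noise around the centimetre-
per-second speeds near contact cannot fragment the approach.

## Constant-r segment detection

The detector operationalizes a threshold-factor criterion: window-regression
statistics must stay within `f` scale parameters of a t-distribution fitted
to their distribution over the track (default `f = 1.5`, sweep utility over
`f ∈ [0.25, 2.5]`). Constant-`r` flight satisfies `V = r*·y`, a ray through
the origin of the `(y, V)` plane, so the detector regresses a 5 Hz-smoothed
`V` on `y` over every sliding window of the minimum plateau duration
(0.1 s). This parameterization was chosen over a regression of `r` on `t`
because its key statistic is level-free — the window intercept is zero on a
plateau at *any* set-point — and because its noise does not blow up as
`1/y` near contact, where `r` itself becomes uninformative. Six statistics
are collected per window: the fractional ray offset (intercept divided by
the window's mean speed, which equals ~`ṙ/r²` during a transient), the
studentized intercept, and four noise-level statistics (residual scale, the
two standard errors, lag-1 residual autocorrelation).

Acceptance details, in order of application:

- Windows whose mean approach speed is below 0.02 m/s are indeterminate
  (the ray geometry is lost in tracking noise) and never accepted.
- Each statistic's location and scale come from a df = 3 t-distribution
  fitted to the *core* of its distribution over windows, isolated by
  iterated MAD trimming — the raw distribution mixes the plateau core with
  a continuum of transient values and a plain heavy-tailed MLE inflates the
  scale badly.
- Scale floors (0.02 on the fractional offset, and analogous small floors
  on the others) absorb the deterministic residue of zero-phase filtering,
  which offsets an exponentially decaying `V` by ~`(r/ω_c)²` even on
  noise-free data.
- Standardized deviations are averaged over ±4 neighbouring windows before
  thresholding, so single-window noise cannot fragment a plateau while a
  transient's sustained deviation still rejects it.
- The two ray-offset statistics gate at `f`; the noise statistics act only
  as outlier guards at `4f` (all bounds scale with `f`, so coverage is
  monotone in `f` by construction).
- An absolute cap on the fractional ray offset (0.15 plus a noise
  allowance) guards against tracks in uniform transit, where every window
  looks alike and a purely relative criterion would accept everything.
- Accepted windows merge into maximal runs (gaps of up to two windows
  tolerated); fragments with mean `r` within 2% reunite; each segment's
  onset is then refined to the earliest contiguous sample within 5% of the
  segment's settled level (extending backward over settled samples the
  window grid missed, but only while the filtered `r` is locally flat, so a
  steep flanking ramp is never swallowed).

The detector sits behind a plug-in interface
(`detect_constant_r(..., detector=...)`) so the original published
set-point algorithm can be substituted; exact reproduction of published
segment counts is only expected with that detector.

## Entry segments

For each plateau, the entry is the maximal run of the 5 Hz-filtered `r`
monotone (tolerance 0.02 1/s per sample) into the plateau's first sample,
trimmed at its head to where the local rate first exceeds 15% of the run's
peak rate — the "monotonic variation" should not include the asymptotic
tail of the previous plateau or the acausal smear of the zero-phase filter.
Increasing runs that began below 0.5 1/s start instead at the interpolated
0.5 1/s crossing (snapped to the nearest sample); the rule is applied to
increasing runs only. A run whose net step is below 15% of the set-point is
discarded as drift at the noise floor. Entries end exactly one sample
before their plateau.

## Transient characterization

The expansion-acceleration `ṙₑ` is the OLS slope of the **5 Hz-filtered**
`r` over the entry (the track is filtered whole, then sliced, to avoid edge
transients). The set-point dynamics live well below 5 Hz and the
high-frequency residue of `r = V/y` is tracking noise; fitting the filtered
signal leaves the slope essentially unbiased (the transition content sits
near 2–3 Hz, costing a few percent of attenuation) while cutting the
estimator's variance several-fold on noisy segments. `R²` is defined as 0
for a constant signal. The model trajectory for the distance discrepancy
and the acceleration-error correlation starts from the measured `y₀` with
`r₀` taken from the regression intercept at the segment's first timestamp
(noise robustness); `Δd` is positive when the animal covered more distance
than the constant-`ṙ` model. The model acceleration `A_e(t) = (ṙ − r²)·y`
along the fitted constant-`ṙ` motion stands in for the doubly
differentiated measured acceleration, which is noise-dominated.

Closed form: with `r(t) = r₀ + ṙt`, distance follows
`y(t) = y₀·exp(−(r₀t + ṙt²/2))`, verified against high-accuracy ODE
integration to 1e-8 m over a grid of `(y₀, r₀, ṙ)`.

## System identification

With a constant input the frequency-domain excitation is degenerate, so
identification is time-domain least squares: the order-n linear ODE is
simulated by exact zero-order-hold discretization (one matrix exponential
per fit, propagated across the uniform grid), and the parameters plus free
initial conditions (output value and derivatives, initialized from the
filtered signal) are optimized by Levenberg–Marquardt from eight
deterministic grid starts spanning `K ∈ [0.6, 1.4]`, `D ∈ [0.25, 2]`,
`w ∈ [4, 45]` rad/s plus one data-driven start — the loss surface has local
minima. Orders 1 and 3 use `K/(τs+1)` and `K·w²/((τs+1)(s²+2Dws+w²))`,
minimal unity-DC-gain extensions of the order-2 form. A fit that fails on
every start carries `F = −∞` and is excluded from summaries. Noiseless
order-2 responses are recovered to machine precision; under 0.05 1/s white
noise plus 5 Hz filtering the median parameter error is ~3% over 100 seeded
replicates.

## Statistical models

The gamma fit is maximum likelihood with location fixed at zero; 95%
intervals come from the inverse Fisher information. The mixed models use
natural logarithms and REML, with crossed random intercepts for day,
approach number and landing side realized as variance components over a
single trivial group (statsmodels `MixedLM`). Optimization uses Powell's
method with a gradient-method cross-check, keeping the better restricted
likelihood: gradient optimizers stall away from the zero-variance boundary
that a factor without real variation must reach (verified against lme4,
which returns exact zeros there). A factor with fewer than two levels, or
whose fitted component is numerically zero, is dropped with a logged
warning; with every factor dropped the model reduces exactly to OLS.
P-values are large-sample Wald (no Satterthwaite/Kenward–Roger refinement).
Predicted means are `exp(x'β̂)` with delta-method intervals, random effects
averaged at zero; the marginalization weights over conditions are the
caller's choice via explicit covariate settings. Post-hoc families:
Bonferroni over the three pairwise light contrasts, and the single
landing-type contrast.

The pipeline feeds the models the entries with positive `Δrₑ` and positive
fitted `ṙₑ` (the study's focus); the `Āₑ` model additionally keeps only
entries with positive mean acceleration.

## Synthetic data: what it emulates, and what it does not

The generator realizes the hypothesized control loop: `r` follows
`r̈ + 2Dwṙ + w²r = w²Kr*` toward the current set-point while `dy/dt = −r·y`,
integrated by classical fourth-order stepping at 8× the sampling rate and
decimated to 175 Hz. Defaults are the study conditions: initial `r*`
lognormal with median 1.5 1/s, multiplicative steps `U(1.3, 2.0)`, 2–4
plateaus, switch after `|r − r*| < 5%·r*` has held for a dwell of
`U(0.15, 0.4)` s, start distance `U(0.25, 0.45)` m, controller `K = 1`,
`D ~ U(0.8, 1.2)`, `w` lognormal with median 15 rad/s (σ = 0.2 of the log;
the scale that makes a ~1.7 1/s step produce expansion-accelerations of
order 10 1/s²), and 0.5 mm white position noise added before filtering.
An explicit `schedule` overrides the set-point draw for known-schedule
recovery studies. Condition effects multiply the natural frequency —
sunrise ×1.10 and medium ×1.03 versus twilight, after-takeoff ×0.97 —
mirroring the reported 9–10% and 3% effect magnitudes. Ground truth records
every set-point, switch time, reach time (first entry into the 5% band) and
the realized transient slope (OLS slope of the noiseless `r` over
switch→reach), which is the reference for slope-recovery tests.

The generator does **not** emulate: lateral manoeuvring (x and z are small
noise paths), wingbeat oscillations, aerodynamics or body rotation,
non-stationary noise of a real videography system, hovering phases or
aborted approaches, or set-point *decreases* (steps are multiplicative
above 1; decreasing entries are exercised with constructed fixtures
instead). Passing the synthetic recovery tests therefore shows the
*estimators* are correct and well-calibrated under the modelled conditions;
it does not certify performance on the real database, where the plug-in
detector interface and the canonical CSV adapter are the intended route.

## Problem sizes in the checks

The end-to-end checks run on cohorts of tens to a few hundred landings:
set-point recovery uses 5 noiseless known-schedule landings; boundary and
slope recovery use 80 landings over the study-scale step (1.1 → 2.78 1/s);
the injected-effect recovery uses 25 replicates of 300-landing cohorts
(~800 entries each, approaching the study's own ~2,600-entry scale, which
is what a 10% multiplicative effect needs to surface reliably through this
noise level); identification recovery uses 100 seeded replicates. The
analysis drivers default to 60 landings so a full narrative run stays in
the minutes range.

## Known limitations

- The constant-`r` detector is this package's operationalization of a
  criterion whose full published definition lives in companion material;
  published segment counts (9,957 segments / 2,776 entries at `f = 1.5`)
  require the original detector plugged in.
- Plateau onsets on asymptotic approaches are intrinsically fuzzy; the 5%
  settled-band convention defines them here, and set-point means carry a
  small low bias (<1%) from convergence tails.
- `ṙₑ` from the filtered signal trades a few percent of attenuation for a
  large variance reduction; with very fast controllers (`w` approaching the
  5 Hz filter band) the attenuation grows and condition-effect estimates
  shrink accordingly.
- The mixed models' p-values are large-sample; with few random-factor
  levels (e.g. two landing sides) the variance components are weakly
  identified, as in any lme4-style fit.
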