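# beeland

Analysis of how landing bumblebees steer their final approach by regulating
the **relative rate of optical expansion** — and a closed-loop simulator to
test every stage of that analysis against known ground truth.

When an animal approaches a surface head-on, the image of the surface
expands on its retina at the relative rate

    r(t) = V(t) / y(t)        [1/s]

where `y` is the perpendicular distance to the surface and `V = -dy/dt` the
approach speed (`r` is the inverse of the time-to-contact). Bumblebees do
not hold one `r` for the whole landing: they fly short bouts at a constant
set-point `r*`, then step the set-point up as the surface nears. Each step
excites the closed sensorimotor loop, and the transient "entry segment"
leading into the next constant-`r` bout is that loop's step response.

The package implements the full chain:

1. **trajio** — canonical track I/O at 175 Hz, zero-phase 20 Hz Butterworth
   filtering, touchdown alignment.
2. **kinematics** — state estimation `y, V, A, r` by second-order central
   differences, and the expansion-acceleration identity
   `dr/dt = (yA + V²)/y²`.
3. **segmentation** — detection of constant-`r` segments under a
   threshold-factor-`f` criterion (default `f = 1.5`), and extraction of the
   monotone entry segments that precede them (an increasing entry starts at
   the `r = 0.5 s⁻¹` crossing or the onset of monotone variation, whichever
   is later).
4. **sysid** — transfer-function identification of each (entry, constant-r)
   pair, input `r*(t)`, output the 5 Hz-filtered `r_f(t)`; order 2 is
   `r_f(s)/r*(s) = Kw² / (s² + 2Dws + w²)`, scored by the fit percentage
   `F = 100·(1 − ‖r_f − r_s‖ / ‖r_f − mean(r_f)‖)`.
5. **transient** — each entry as motion at constant expansion-acceleration
   `ṙₑ` (slope of the regression `r(t) = ṙₑt + c + ε`), with the closed-form
   trajectory `y(t) = y₀·exp(−(r₀t + ṙt²/2))`, the flight-distance
   discrepancy `Δd`, the mean approach acceleration `Āₑ = ΔV/Δt`, and the
   correlation between the model acceleration and the set-point error.
6. **stats** — gamma fit of the `ṙₑ` distribution and two log-linear mixed
   models (REML; random intercepts for day, approach number, landing side):
   `log(M) ~ log(y₀) + medium + sunrise + after-takeoff + log(Δrₑ) +
   log(r*) + log(y₀):log(Δrₑ)` for `M ∈ {ṙₑ, Āₑ}`, with Bonferroni-adjusted
   contrasts and back-transformed predicted means.
7. **synthetic** — a closed-loop landing generator: `r` follows second-order
   dynamics toward the current `r*`, position follows `dy/dt = −r·y`,
   set-points step upward on a schedule, and tracking noise (0.5 mm) is
   added. Every plateau and switch is recorded as ground truth.

## Worked example

```
python analysis/01_simulate_cohort.py --n 60 --seed 1
python analysis/02_detect_segments.py
python analysis/03_identify_dynamics.py --max-pairs 16
python analysis/04_transient_statistics.py
python analysis/05_mixed_models.py
```

The first two stages print, for the 60-landing synthetic cohort:

```
227 constant-r segments in 60 of 60 maneuvers (f = 1.5)
114 linked entry segments (113 with positive step, 1 negative)
entry medians: dre 0.88 1/s, r* 2.54 1/s, y0 0.19 m
constant-rdot fit: R^2 median 0.988, |distance discrepancy| median 0.21 mm
```

meaning the detector found on average ~4 set-point bouts per landing, almost
every linked transient raised the expansion rate (the synthetic bees, like
real ones, step the set-point up), and the constant-expansion-acceleration
model describes the transients almost perfectly — the linear fit of `r(t)`
explains 98.8% of the variance and the animal's actual flight distance over
an entry differs from the model's by ~0.2 mm. Stage 3 prints the
order-comparison medians (second order captures more variation than first),
and stages 4–5 print the gamma fit of `ṙₑ` and the mixed-model coefficient
tables.

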