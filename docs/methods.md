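# Methods

This note documents the models, estimators and numerical choices behind
`femwalk`, in the spirit of a model-description appendix.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time base and containers

All series are uniformly sampled at Δt = 2 ms (500 Hz) unless stated
otherwise; lags l are integer sample counts and reported in ms as
l·Δt·1000.  A trajectory is an (N, d) array, d ∈ {1, 2}, with column
order (horizontal, vertical); trials of one condition share Δt.  Every
source of randomness is a NumPy generator derived from
`SeedSequence((seed, trial_index))`, so any trial is reproducible in
isolation and bit-identical under re-simulation.

## Non-linear delayed feedback model (NDF)

    w[i+1] = (1 - γ) w[i] + ξ[i] - λ tanh(ε w[i-τ])
    x[i+1] = x[i] + w[i+1] + η[i]

`w` models pooled excitatory-burst-neuron activity (eye velocity), the
leak γ the eyeball's inertia, and the tanh-saturated term a negative
feedback delayed by τ samples; ξ ~ N(0, σ²) is burst baseline noise and
η ~ N(0, ρ²) tonic-unit (position) noise.  Defaults: γ = 0.25,
λ = 0.15, ε = 1.1, σ = 0.075, ρ = 0.35, τ = 35 samples (70 ms,
horizontal) or 20 samples (40 ms, vertical) — the published best-match
set for 500 Hz fixation data.  The 2-D simulator runs two independent
1-D instances on spawned child streams.

Numerics: the activity history is initialised at zero (`w[j] = 0`,
j ≤ 0) and the first `burn_in` samples (default 2,000 ≫ τ) are
discarded, so the output is free of the initial transient.  Output is
in model units; only correlation shapes are compared downstream, not
amplitudes.

## Fading self-avoiding walk (SAW)

An L×L lattice (L = 51) stands for the retinotopic map of the superior
colliculus.  Per 2 ms iteration the walker at site (i, j):

1. deposits one unit of activation at its site, `h[i,j] += 1`;
2. if `h` at its site now exceeds h_c, jumps (microsaccade) to the
   global minimum of `h + u + u₁`;
3. otherwise steps to the von Neumann neighbour minimising `h + u`
   (ties within 1e-12 broken uniformly at random);
4. the whole field decays, `h ← (1 − ε) h`.

with the quadratic restoring potential and microsaccadic potential

    u(i,j)  = L [λ_hor ((i-i₀)/d)² + λ_ver ((j-j₀)/d)²],   d = (L+1)/2
    u₁(i,j) = χ L ((i-i₀)/d)² ((j-j₀)/d)²

Defaults: λ = 1 (isotropic), χ = 2, ε = 10⁻³, h_c = 7.9.  Burn-in:
10,000 iterations from an i.i.d. uniform(0, 1) field with the walker
centred; the burn-in trajectory is discarded and its final state seeds
the recorded run.

Numerical/order choices:

* **Deposit before trigger.**  The threshold test counts the visit's
  own deposit.  This is forced by the parameter set: at the defaults the
  steady-state arrival activation *excluding* the deposit never exceeds
  ≈ 7.0 (h_c = 7.9 would never fire), while including it the value peaks
  at ≈ 8.0 — the threshold is evidently calibrated inside that band.
  Measured microsaccade rate at defaults: ≈ 0.14/s.
* **Neighbourhood.**  The step readout uses the 4-neighbourhood
  {(i±1, j), (i, j±1)}; edge sites use their available neighbours (the
  potential makes edges effectively unreachable anyway).
* **Decay after increment.**  The global decay follows the deposit
  within an iteration; the alternative order differs only at O(ε).
* **Lazy field scaling.**  The field is stored as `h = scale · f` with
  one scalar updated per decay, making an iteration O(1) instead of
  O(L²); the representation performs the same floating-point products
  and renormalises long before underflow.
* Triggers at the lattice core: activation accumulates fastest at the
  potential minimum, so microsaccades fire near the centre and land a
  few sites out, where `h + u + u₁` is globally minimal.

## Time-delayed SAW variants (D-SAW)

A delay of τ iterations (explored band 10–18, i.e. 20–36 ms) applies to:

| variant | delayed quantity                     |
|---------|--------------------------------------|
| DS      | activation state used for readout    |
| DR      | position at which the step is read   |
| DA      | position at which activation is set  |
| DAR     | both positions                       |

Read-out noise: every position consumed for a readout or a delayed
activation setting receives per-coordinate Gaussian noise
δ ~ N(0, 0.3²), rounded to the nearest integer and clamped to the
lattice (≈ 9.6% displacement probability per coordinate).  The noise
prevents DR/DAR trapping in confined trails and is applied in all
variants so they remain comparable; in DS/DA it acts on the current
readout position — without it the delayed-deposit walkers ping-pong
between two sites (their own recent deposits are invisible), which
produces a parity artefact incompatible with the diffusive behaviour
these variants are meant to show.

Mechanics decisions where the printed description is open:

* **DR/DAR step application.**  The argmin over the delayed site's
  neighbourhood yields a *relative* step applied at the walker's true
  position (clamped); moving the walker next to the delayed site would
  teleport it and violate the unit-step rule.
* **DAR** draws one noisy delayed position per iteration and uses it for
  both the readout and the activation setting.
* **Triggering.**  DR/DA/DAR test the *current* field at the *current*
  position (delay-free efference-copy signal).  DS — whose premise is
  that the walker reads a delayed activation state — uses the delayed
  field for both the threshold test and the jump-target readout; with a
  current-field trigger DS fires ≈ 50 microsaccades/s and departs from
  DA by an order of magnitude in MSD level, whereas the delayed-field
  trigger restores the expected DS ≈ DA equivalence.
* **Variant burn-in.**  During the first τ burn-in iterations (buffer
  filling) DS/DR/DAR step uniformly at random among available
  neighbours; DA/DAR additionally pause the activation setting and the
  global decay.  Buffers carry into the recorded run.  At τ = 0 with
  noise off every variant is bit-identical to the plain walk (shared
  RNG consumption order; asserted in tests).
* h_c defaults to 17.5 for DR/DAR (midpoint of the published 15–20
  adjustment band) and 7.9 otherwise.  Note: under the relative-step
  mechanics our DR/DAR walkers sweep wide orbits and their activation
  peaks stay below 15, so they fire no microsaccades at those
  thresholds; the variant comparison rests on MSD/DACF shape, which is
  insensitive to this.

## Correlation analysis

MSD and the k-interval DACF (k = 25 samples = 50 ms) are time averages
per trial, then averaged pointwise across trials (never across
concatenated trials); per-lag SDs across trials serve as error bars.
The DACF is normalised at lag 0.  Scaling exponents are OLS slopes of
log₁₀ MSD versus log₁₀ lag over inclusive windows of 2–12 ms (short
scale) and 120–1200 ms (long scale), all integer lags included.

Oscillation metrics: the first maximum of an averaged DACF is the
smallest lag after the first sign change at which the curve is a strict
discrete local maximum with value above a floor of 0.05.  The floor
rejects estimator noise: trial-averaged DACFs of non-oscillating walks
fluctuate around zero at the 0.01 level, and model discrimination
hinges on presence/absence of a genuine secondary peak.  "No
oscillation" is a first-class result, not an error.  The period T is
identified with the first-maximum lag, and the implied feedback-delay
bracket is (T/4, T/2), inverting 2τ < T < 4τ.

The anisotropic-potential comparison (λ_hor = 0.9, λ_ver = 1.1, DAR)
uses τ = 14 (28 ms), mid-range of the explored band: at τ = 18 the DAR
oscillation is so strong (DACF peak ≈ 0.9) that it becomes a
near-deterministic limit cycle phase-locking both components to a single
period, while for τ ≤ 16 the horizontal-slower-than-vertical ordering
of first-maximum lags is robust across seeds.

A caveat for lattice walks: the 2–12 ms fit window of DS/DA overlaps the
residual two-sample parity structure of near-bouncing lattice motion and
reads ≈ 0.7; over 10–100 ms, where the power law is clean, the same
curves fit at 0.9–1.0 ("almost uncorrelated").  Both windows are
reported by the acceptance script's discrimination summary.

## Preprocessing

Velocities use the five-sample weighted moving average
`v[i] = (x[i+2]+x[i+1]-x[i-1]-x[i-2])/(6Δt)` with symmetric central
differences at the two interior endpoints; smoothing is the cumulative
re-integration `x_s[i] = x[1] + Δt Σ_{j<i} v[j]`.  The printed
convention implies a one-sample time shift (on linear data the output
reproduces x[i−1] at i), irrelevant to the time-averaged MSD/DACF.

Detection uses the elliptical threshold `(v_x/η_x)² + (v_y/η_y)² > 1`
with η = λσ, λ = 5, and a *median-based* spread
σ² = median(v²) − median(v)² per component (robust to the
microsaccades themselves; non-positive values raise a degenerate-
threshold error).  An episode is a maximal run of ≥ 3 suprathreshold
velocity samples (6 ms); runs separated by any subthreshold sample stay
distinct; thresholds are recomputed per trial.  Binocular confirmation
keeps a left/right pair iff `r_end > l_onset` and `r_onset < l_end`
(strict, as printed: episodes merely touching at one endpoint do not
overlap), and emits the union interval.  Removal deletes the episodes'
velocity samples and re-integrates, shortening the trajectory.

## Synthetic trials

The generator emulates binocular 500 Hz fixation recordings: 30 trials
× 10,000 samples (20 s).  Drift comes from the 2-D NDF (delays 35/20)
scaled by 0.0074 deg per model unit so the drift's positional SD is
≈ 0.1 deg, at the top of the physiological drift range (0.02–0.1 deg);
a Brownian drift source (step SD 0.0015 deg) is available.
Microsaccades arrive as a Poisson process at 1.5/s with a 100 ms
refractory gap, amplitude ~ N(0.5, 0.1²) deg over 24 ms with a
raised-cosine velocity profile, and *corrective* direction: towards the
fixation centre, snapped to the axis carrying the larger error.  The
corrective geometry is what makes microsaccade removal raise the
long-scale exponent, as observed in recordings; with random directions
the ordering would not hold.  The right eye shares drift and
microsaccades up to a ±1-sample onset jitter, with independent
measurement error.

Measurement error is the instrument's finite spatial resolution:
positions are quantised to a 0.01 deg grid after an independent
sub-resolution tracker jitter (SD 0.0025 deg) per eye.  Modelling the
resolution as white noise of SD 0.01 deg instead would inject far more
high-frequency power than real recordings carry — it alone contributes
~20% of the 50 ms displacement power, which the smoothing then removes,
changing the normalised DACF by ~0.3; under quantisation the change is
< 0.01, matching the observed insensitivity of recorded DACFs to
smoothing.

What passing fixture tests do **not** show about real data: the
generator contains no tremor, no main-sequence amplitude–velocity
relation, no blinks, and no participant-level variability; detection
performance on it bounds the pipeline's correctness, not its field
sensitivity.

## Problem sizes

Simulation batches follow the study conditions: 30 trials × 10,000
steps per model/condition; the anisotropy comparison repeats 5 seed
replicates of such batches; estimator-oracle checks use 100 random
trajectories of ≤ 200 samples.  The full test suite runs in about a
minute on one CPU; `scripts/acceptance.py` in about two.

## Known limitations

* DR/DAR fire no microsaccades at h_c ∈ [15, 20] under the relative-step
  readout mechanics (activation peaks ≈ 13); an absolute-move reading of
  the delayed readout would change this but violates the unit-step rule.
* The lattice models' 2 ms discreteness leaves parity structure in the
  shortest-lag MSD of the delayed-deposit variants (see above).
* No EyeLink/EDF ingestion: tabular text only.  No parameter fitting of
  any model to data; the published parameter sets are taken as given.
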