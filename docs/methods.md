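# Methods

This note records the models, conventions and numerical choices behind
`hdtheta`, and what the synthetic validation does and does not establish.

## Coordinate and sign conventions

Arenas are centred on the origin; positions are in cm, times in seconds.
Head direction is the mathematical bearing of the front-minus-back LED
vector: counter-clockwise positive, 0° along +x, wrapped to \[0, 360).
Angular head velocity is reported **clockwise-positive** (the negated time
derivative of the bearing), so the +120°/s threshold selects clockwise head
turns. Screen-coordinate pipelines often invert this sign; every threshold in
the package assumes the CW-positive convention. All angle-valued summaries
use circular statistics: circular means, circular differences in (−180, 180].

## Synthetic sessions

The generator exists to produce data with exactly the statistical structure
the analyses assume, with known ground truth.

**Trajectory.** Speed and angular velocity follow stationary
Ornstein–Uhlenbeck processes (speed: mean 20 cm/s, SD 8 cm/s, correlation
time 1 s, clipped at 1 cm/s; angular velocity: mean 0, SD 160°/s, correlation
time 0.5 s), integrated at the 50 Hz tracker rate with specular reflection at
the arena wall (1 cm margin). These values describe a brisk pellet-chasing
rat; the angular-velocity SD guarantees a substantial fraction of samples
beyond the ±120°/s CW/CCW threshold, as in real foraging. Two LEDs sit 6 cm
apart along the heading axis (the tracker geometry is a fixture — only the
LED-difference direction matters downstream). Twenty-minute sessions cover
≥ 90 % of 2.5 cm bins and all 72 directional bins, so the inclusion rules
pass as they would for a usable recording. A zero-duration request returns a
single-sample trajectory (documented degenerate convention).

**Spike trains** are inhomogeneous Poisson processes generated by thinning
(candidates at the intensity ceiling, acceptance ∝ λ(t)); identical inputs
and seed give bit-identical output.

- Head-direction cell: λ(t) = b + A·exp(κ(cos(θ(t) − θ_p(t)) − 1)), with
  θ_p shifted ±offset/2 by the sign of the (smoothed) angular velocity, so
  the full CW−CCW separation equals the offset parameter. Defaults: κ = 4,
  A = 30 Hz, b = 0.5 Hz — a well-isolated, strongly tuned unit.
- Place cell: λ(t) = b + A·exp(−|x(t) − c|²/2σ²), default σ = 8 cm,
  A = 20 Hz.
- Theta / theta-cycle-skipping cell:
  λ(t) = r0·\[1 + m1 cos(2πf t) + m2 cos(πf t)\], default f = 8.67 Hz,
  r0 = 5 Hz, m1 = 0.6, m2 = 0.4 (clipped at zero should the depths ever sum
  past 1). The half-frequency term attenuates alternate theta cycles —
  precisely the superposition the autocorrelogram model is built to recover.
  For second-order statistics, the intensity autocovariance contributes
  cosine components proportional to m²/2 at f and f/2, so the expected
  jump factor of the default generator is m2²/(m1² + m2²) ≈ 0.31.

What the generator does **not** emulate: head direction decoupled from
movement direction (the simulated animal always "looks where it walks",
apart from the OU jitter), drift or cue rotation, bursting/refractory spike
structure, electrode drift, cluster-cutting contamination, or LFP coupling.
Passing tests therefore validate the estimators against their own model
class, not against every failure mode of real recordings.

## Estimators and conventions in the analysis

- **Tuning curves**: spikes assigned the heading of the nearest tracker
  sample (no interpolation); rate = spikes/dwell per 5° bin. Curves are only
  computed when every directional bin was sampled.
- **Normalisation**: rates divided by the peak and circularly shifted so the
  maximal bin is the bin containing 180°.
- **CW/CCW split**: samples (and their spikes) at ω ≥ +120°/s form the CW
  curve, ω ≤ −120°/s the CCW curve (boundary samples included); slower
  samples belong to neither. Split-curve rates are spikes per visit (a visit
  = an entry of the thresholded sample subsequence into a bin); the
  dwell-based rate is carried alongside.
- **Preferred direction and separation**: the headline "preferred direction"
  is the circular mean of spike headings, and the separation angle is the
  circular difference of the CW and CCW rate-weighted mean directions. At 5°
  bins the argmax of a near-flat tuning top moves ±2–3 bins under shot noise
  (adjacent bins differ by ~1.5 % in rate at κ = 4 against ~4–5 % count
  noise in a 20-min session), so peak-bin estimates cannot resolve one bin;
  the mean-based estimators recover the generator's preferred direction to
  ≤ 1.3° and a 20° separation to ≤ 2.2° across seeds. The literal peak-bin
  directions remain available (they are also what the condition comparison
  uses for "peak HD", mirroring the reported measure).
- **Angular-velocity estimator**: central difference on the unwrapped
  heading with a 5-sample boxcar (default on); NaN samples (coincident LEDs)
  are linearly interpolated before differencing and excluded from occupancy.
- **Rayleigh p-value**: the standard approximation
  p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)).
- **HD-cell criterion** for classification: Rayleigh r ≥ 0.4, p < 0.01 and
  ≥ 100 spikes — a documented convention (no quantitative criterion exists
  in the source taxonomy), configurable in `SessionConfig`.

## Spatial metrics

A "pixel" is one occupancy bin. Coverage/inclusion uses 2.5 cm bins; metric
maps (information, selectivity, fields) default to **5 cm** pixels. At 2.5 cm
a 20-min session leaves ~1 s of dwell per pixel, and the unsmoothed Skaggs
information of a *directionally* tuned but spatially untuned unit comes out
around 0.29 bits/spike — dominated by shot noise plus the wall-heading
correlation every reflecting walk (and every real rat) exhibits. At 5 cm
(~4 s dwell/pixel) the same unit measures ~0.1 bits/spike, and place cells
remain unmistakable (> 2 bits/spike). No smoothing is applied by default; an
optional boxcar exists for both counts and dwell.

Place fields are side-sharing (4-connected) components of pixels above 20 %
of the map peak, at least nine pixels in size, **and** with a mean in-field
rate at least twice the map's mean visited-pixel rate. The contrast
requirement is needed because the threshold rule alone marks a "field" for
any uniformly firing unit (its entire map sits above 20 % of a peak close to
the mean); a field is by definition a region of *elevated* firing. Setting
`min_contrast=0` restores the plain threshold rule. Unvisited pixels are
excluded from the peak, the mean, the information sum and field detection;
rates are defined wherever dwell exists, and the arena mask scopes the
metrics.

Spatial information uses dwell-fractions p_i over visited in-arena pixels and
the dwell-weighted mean rate λ̄; zero-rate pixels contribute zero; a silent
unit has undefined information and selectivity (explicit error, not 0).

## The autocorrelogram model

The autocorrelogram counts all ordered spike pairs with lags in ±1000 ms at
1 ms bins (bin centres at integer ms; zero-lag self-pairs excluded; symmetric
by construction). The model

y(x) = \[a1 cos(ω1 x) + a2 cos(ω2 x)\]·e^{−|x|/τ1} + b + c1 e^{−|x|/τ2} − c2 e^{−|x|/τ3}

mixes units deliberately: the cosine arguments take the lag in **seconds**
with ω in rad/s — so the bounds ω1 ∈ \[12π, 24π\] and ω2 ∈ \[6π, 12π\] mean
6–12 Hz and 3–6 Hz — while the exponential arguments take the lag in **ms**
with τ1 ∈ \[0, 5000\], τ2 ∈ \[0, 100\], τ3 ∈ \[0, 10\] ms. Amplitudes a1, a2,
b, c1, c2 are bounded by \[0, N\], N the autocorrelogram peak. The (c1, τ2)
term carries the Poisson-ISI exponential, (c2, τ3) the refractory dip, and
the two decaying cosines produce alternating high peaks (in-phase) and low
peaks (anti-phase) without assuming an exact 2:1 frequency lock — the fitted
ratio ω1/ω2 is itself the check of the superposition model.

Numerical choices:

- τ lower bounds are 10⁻² ms rather than 0 (e^{−|x|/τ} is singular at τ = 0;
  at 1 ms binning the difference is invisible).
- The model is even in x and the autocorrelogram symmetric, so the residual
  is evaluated on the non-negative lags only; the optimum is identical and
  the fit twice as fast.
- Multi-start: a 5 × 5 grid of (ω1, ω2) initial values interior to their
  bounds; the other parameters are initialised from signal statistics (b from
  the ≥ 800 ms tail mean, c1 from the 3–30 ms mass above b, c2 from the
  centre-bin deficit, a1 + a2 from the first-peak excess over b; τ's at
  300/30/2 ms). Best residual wins; bounded trust-region least squares
  (`scipy.optimize.least_squares`, trf). The whole multi-start fit takes
  ~1–3 s per unit.
- Identifiability: on noiseless curves all ten parameters are recovered to
  machine precision. Under Poisson count noise at N ≈ 500 the six rhythm
  parameters (a1, a2, b, ω1, ω2, τ1) recover to < 10 %, but the transient
  pairs (c1, τ2) and (c2, τ3) trade off against each other (few informative
  bins near lag 0) and can individually err by tens of percent even at the
  global least-squares optimum. The derived indices do not depend on them.
- Count realism: Poisson-noise validation only makes sense for parameter
  sets whose curve is non-negative everywhere (counts cannot be negative);
  amplitude sets that dip below zero get distorted by clipping before
  sampling, biasing any fit.

**Indices.** Jump factor a2/(a1+a2) (undefined at a1 + a2 = 0); frequency
ratio ω1/ω2 (∈ \[1, 4\] by the bounds). The theta-skipping index
TS = (P2 − P1)/max(P1, P2) is measured on the first two post-centre local
maxima of the **fitted rhythmic envelope** — the cosine terms times their
decay plus b, with the transient exponentials excluded, because the
refractory-rebound of the c-terms can otherwise produce a spurious local
maximum at ~10 ms that is not an oscillation peak. A raw-counts mode exists
(`use_fitted=False`), searching lags ≥ 40 ms (the slowest admissible theta
puts the first peak at 83 ms). TS ∈ \[−1, 1\] by construction; it is
undefined (explicit error) when fewer than two maxima exist, e.g. for an
unmodulated fit.

**Skipping classification** (convention, configurable): converged fit, TS > 0,
jump factor ≥ 0.2, and a1 + a2 above a noise floor estimated from the flat
tail (amplitude equivalent of 3 tail-SDs, √(2/n)-scaled). At the default
generator (m1 = 0.6, m2 = 0.4) the expected jump factor is ≈ 0.31 with
seed-to-seed SD ≈ 0.07, so occasional seeds fall under the 0.2 threshold;
18–20 of 20 seeds classify positive, and pure-theta (m2 = 0) and homogeneous
Poisson units classify negative.

## Classification taxonomy

Precedence: hd > theta_skipping > spatially_tuned > theta_modulated >
fast_firing > weakly_theta_modulated > unidentified_low_firing. The non-HD
thresholds are package conventions, all in `SessionConfig`: spatially tuned
requires ≥ 1 place field and ≥ 0.5 bits/spike; theta modulation strength is
a1/(a1 + b) from the autocorrelogram fit with bands 0.3 (modulated) and 0.1
(weak); fast firing is > 10 Hz average rate. Cross-day matching is greedy
nearest-neighbour on z-scored (amplitude, height, duration) with a normalised
distance ceiling of 1.

## Condition comparisons

Five measures per unit (mean HD, CW and CCW mean HD, peak HD, peak rate) are
compared across paired conditions by one-sample t-tests on per-unit
differences — circular differences for the angular measures — at a
Bonferroni-adjusted level α/5. Identical conditions return t = 0, p = 1
rather than 0/0. With ~10 stable units, tuning that is genuinely unchanged
between conditions yields no significant measure, reproducing the
light/dark and circle/square null behaviour the analysis is designed to
demonstrate.

## Problem sizes used in validation

Tests and the acceptance script use 20-minute sessions at 50 Hz for
behavioural analyses, 10-minute trains for autocorrelogram fits, 20 seeds for
population-level recovery claims, and 10 units for condition nulls. These
sizes put shot noise well below every tolerance asserted while keeping the
whole suite a couple of minutes long.

## Known limitations

- The generator's heading equals movement direction; analyses that would
  dissociate them (e.g. egocentric-bearing controls) have no synthetic
  counterpart here.
- The TS index depends on the fitted envelope; raw-counts TS is noisier and
  can disagree near zero.
- Place-field geometry (size in pixels) depends on the metric pixel size;
  cross-study comparisons need matched binning.
- Waveform statistics for cross-day matching are modelled as abstract
  positive features; no spike-shape extraction is implemented.
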