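# Methods

## Model and assumptions

`aeroloc` localizes a transient sound source from the differences in its
arrival time at N ≥ 5 synchronized microphones.  The physical model is
deliberately minimal:

- straight-ray propagation at a single constant sound speed *v* (no
  temperature-gradient refraction, no wind advection);
- spherical spreading only: received amplitude = source level (referenced
  to 1 m) divided by range, with no frequency-dependent atmospheric
  absorption;
- omnidirectional source and microphones;
- a stationary source during one call (tens of milliseconds), so no Doppler
  within a call;
- additive white Gaussian ambient noise, independent per channel.

Each measured lag `l_ij` (samples) between mics *i* and *j* constrains the
source to one sheet of a hyperboloid of revolution about the pair axis.
Because lags are integers, the observable is quantized: a pair separated by
*d* supports only `l_max = d/(v/τ)` distinct nonzero magnitudes, and
`l_max − 1` intermediate hyperboloids between the degenerate bisector plane
(lag 0) and pair axis (lag `l_max`).  This count is the resolution model
used for array design: vertical aperture buys vertical resolution.

## Lag estimation

Channels are band-pass filtered to the call's frequency band with a
zero-phase (forward–backward) 4th-order Butterworth filter — zero-phase so
filtering cannot shift correlation peaks; the effective order is doubled.
Lags are the argmax of the FFT cross-correlation normalized by the product
of segment energies, searched only within the physically possible window
`±(separation·τ/v + 2)` samples for each pair.  Peak ties within 1e-9 are
broken to the smallest |lag|, then negative before positive, so output is
deterministic.  Parabolic sub-sample interpolation exists behind a flag but
is off by default: the integer-sample resolution model is the default
observable.

A call is usable only when every channel detects it.  Detection is
automated as: peak correlation against the reference channel ≥ `min_peak`
(default 0.3; the global-energy normalization makes short quiet calls in
long noisy segments score low, which is the intended screening behavior).
A rejected call returns its full per-channel diagnostics rather than an
exception.

Segments around a scheduled emission time are padded by the maximum
propagation delay (default 175 m / v ≈ 0.51 s) plus the largest pair-lag
bound plus the template duration, so every true arrival falls inside every
channel's segment.

## Solver

1. **Linearization.**  With reference mic *ref* and range differences
   `δ_i = v·l_i/τ`, squaring `|s − m_i| = R_ref + δ_i` and subtracting the
   reference equation leaves a system linear in `(x, y, z, R_ref)`, solved
   by `numpy.linalg.lstsq`.  Infeasible inputs (|δ| exceeding the pair
   separation by more than 0.1 m) raise an error naming the pair.  A design
   matrix condition number above 1e8 flags the estimate `ill_conditioned`;
   a negative recovered `R_ref` is flagged, reflected to its magnitude and
   passed on — the linear stage is only an initializer.
2. **Gauss–Newton refinement.**  Damped (step-halving) Gauss–Newton on the
   true hyperbolic residual `r_i = |s−m_i| − |s−m_ref| − δ_i`, terminating
   on a 1e-9 m step or 50 iterations.  The line search guarantees the
   returned residual never exceeds the initial one; on failure to improve
   the initial estimate is returned flagged.
3. **Flags, not censoring.**  Below-ground solutions are reported with a
   `below_ground` flag rather than clamped or discarded: near-ground
   retrievals are a diagnostic of ground-based interferers (insects, wind
   noise), not a numerical failure.  A corrupted lag set (typically a tonal
   call slipping by whole periods on some channels) can leave only a
   *direction* constrained, driving the least-squares minimum to absurd
   range; an estimate whose reference range exceeds twice the configured
   maximum range is flagged `out_of_bounds`.  Flagged retrievals stay in
   the retrievals table for auditing but are excluded from truth-comparison
   statistics by the pipeline commands and the reproduction script.

Six microphones give five equations for four unknowns; least squares is
used throughout rather than an exact 5-equation solve, for robustness to
quantization and noise.  The reference channel defaults to the first in
layout order and is configurable.  The solver consumes the five
reference-relative lags; the full 15-pair antisymmetric lag matrix is
computed for diagnostics (antisymmetry and triple-closure checks) only.

### Independent oracle

`grid_oracle` minimizes the same residual by brute force: a coarse
exhaustive scan of the search box seeds several well-separated candidates;
each then pattern-searches, walking its evaluation box downhill at each
grid scale before shrinking the step, and finishes with a Nelder–Mead
simplex polish.  The walking and the simplex stage are both needed because
the residual surface of a distant source forms a long, shallow, *curved*
valley that an axis-aligned grid cannot descend to the floor.  The oracle
shares no code with the linear or Gauss–Newton stages and is used in tests
to verify the chain and to bound quantization error (solving at the
corners of the per-pair one-sample rounding cube).

## Synthetic validation experiment

The simulator emulates a tethered-balloon validation flight: a speaker
broadcasting an 11-template loop (ten species-like calls plus one synthetic
tone) at 3 s intervals while drifting through a cylinder of airspace, with
a collocated GPS logging position every 7 s at 5 m per-axis accuracy.
Conditions and defaults:

| parameter | default | why |
| --- | --- | --- |
| call interval | 3 s | broadcast-loop cadence of the emulated experiment |
| GPS interval | 7 s | truth-fix cadence of the emulated experiment |
| horizontal bound | 105 m | maximum horizontal excursion emulated |
| vertical bound | 140 m | maximum height emulated |
| GPS per-axis sigma | 5 m | consumer-GPS accuracy; Euclidean band √3·5 ≈ 8.66 m |
| sample rate | 22,050 Hz | recorder rate of the reference deployment |
| sound speed | 340 m/s | near-surface nighttime air |
| trajectory | integrated random walk, ~2 m/s, reflected at bounds | the real flight path is unknown; speed is a walking-pace tether |
| minimum height | 10 m | keeps the source above the towers; not a measured value |
| source level | 30 (linear, at 1 m) | gives realistic SNR across the cylinder |
| ambient noise RMS | 0.05 (ensemble runs), 0.01 (demo) | produces mixed per-template detectability, as in real screening |
| template bank | 11 bands/durations within 1–9 kHz, 15–100 ms | plausible flight-call envelope; synthesized, not recordings |

Rendering supports two delay modes.  `nearest_sample` (default) rounds each
channel's arrival to the closest sample — exactly the quantized observable
a recorder produces, and the mode under which measured lags provably equal
the differences of per-channel rounded arrival times.  `fractional`
applies exact sub-sample delays by FFT phase shift, for testing the solver
against unquantized truth.

What the simulator does **not** reproduce: real call spectro-temporal
structure, atmospheric absorption (so high-frequency calls are not
penalized with range), speaker directionality, wind drift, multipath and
ground reflections, and correlated noise (insect choruses are rendered as
optional discrete ground-level events instead).  Passing tests therefore
demonstrate the correctness of the lag-to-position mathematics and the
screening logic under controlled conditions — not field-grade detection
performance.

A physical caveat the tests respect: narrowband tonal templates are
genuinely ambiguous under cross-correlation (the peak can slip by integer
multiples of the tone period), so exact round-trip lag assertions use
broadband chirp templates; tones participate in the statistical ensembles
where such slips are part of realistic error.

## Validation statistics

Retrievals are paired with truth interpolated linearly to each call time
(calls more than 10 s outside the track are dropped and counted; the truth
cadence of 7 s makes interior gaps at most 3.5 s).  Errors are decomposed
as signed per-axis differences and the Euclidean norm; summaries report
median, mean, quartiles, Tukey 1.5·IQR whiskers and outliers, and the
fraction of retrievals within caller-specified thresholds — "within the
truth sensor's accuracy" means |Δz| ≤ 5 m per axis and ≤ 8.66 m for
Euclidean distance.  Per-call-type grouping exposes detectability and
accuracy differences between templates.

## Numerical choices

- `max_lag` floors `d/Δd` with a relative tolerance of 1e-9 so decimal-exact
  ratios (1.54/0.154 = 10) are not broken by binary floating point.
- Pair lag search bounds use the ceiling of `separation·τ/v` plus a
  2-sample margin.
- Infeasibility tolerance on |δ| vs separation: 0.1 m (one-sample rounding
  at the bound).
- The grid oracle's default box is ±150 m horizontally, −5..150 m
  vertically, coarse step 10 m, shrink factor 5, four refinement levels
  (final step 16 mm), simplex tolerance one tenth of the final step.
- Recordings are rendered with a 1 s pre-roll (`start_time = −1`) in the
  pipeline commands so segments around calls scheduled at t = 0 fit inside
  the recording; WAV files carry no timestamp, so `localize` takes the
  start time as an option.
- Problem sizes in the test suite and acceptance script (100-call exact
  ensembles, 50-case oracle comparisons, 200-call noisy ensemble, 300 s
  acceptance experiment) were chosen as the smallest sizes at which the
  statistical properties under test are stable.

## Known limitations

- Constant sound speed: vertical temperature gradients and wind shear bias
  real retrievals, increasingly with height; joint atmosphere-and-source
  estimation is out of scope.
- Microphone positions are assumed exact; surveying error maps directly
  into retrieval error, and acoustic self-survey is not implemented.
- The screening statistic (global-energy normalized peak) conflates SNR
  with call duration; a matched-filter or sliding-window normalization
  would detect short calls at lower SNR.
- Sub-sample lag refinement is available but untested against real
  hardware clock jitter.
- The two-root ambiguity of closed-form TDOA solutions is handled by least
  squares + refinement rather than explicit root selection; the grid
  oracle guards against wrong-basin convergence in tests, not in
  production runs.
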