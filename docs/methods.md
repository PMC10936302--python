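# Methods

## The model and its assumptions

Walking with constant intended speed is modeled as a cyclostationary
random process: the vector of `m` sensor measurements at timestep `k` of
gait phase `φ ∈ {LDS, LSS, RDS, RSS}` is multivariate Gaussian,
`x ~ N(μ_{φ,k}, Σ_{φ,k})`, with a separate cell for every (phase,
timestep). Cells are assumed mutually independent — no correlation is
modeled between neighboring timesteps. That assumption is wrong in detail
(joint angles are smooth in time) but it is what makes the model converge
from minutes rather than hours of data: each cell needs only as many
observations as gait cycles walked, and the estimates are plain sample
means and divide-by-n covariances.

Each cell is updated one observation at a time,

    μ_n = μ_{n−1} + (x − μ_{n−1})/n
    Σ_n = (n−1)/n · Σ_{n−1} + (n−1)/n² · (x − μ_{n−1})(x − μ_{n−1})ᵀ

which reproduces the batch maximum-likelihood estimates exactly (this is an
oracle-tested invariant, not an approximation). Divide-by-n rather than
n−1 is deliberate: the cells are maximum-likelihood Gaussians, and the
squared Mahalanobis distance of in-distribution frames then has mean `m`
up to a known O(m/n) inflation for out-of-sample frames.

Novelty detection uses the squared Mahalanobis distance
`d² = (x−μ)ᵀ(Σ + λI)⁻¹(x−μ)`, computed via a Cholesky solve (no explicit
inverse). For Gaussian frames d² ~ χ²(m), so a detection threshold is
chosen on the χ² CDF scale: the default 13.5 corresponds to CDF 0.99 at
m = 4. The d² stream is smoothed by a causal first-order Butterworth
low-pass before thresholding; smoothing suppresses the heavy right tail of
the per-frame χ² draw that would otherwise toggle the detector.

Timing carries independent evidence of intent change. During training the
model records each phase's length distribution (in timesteps) and the gait
cycle duration distribution (anchored at the start of a reference phase,
LDS by default). At run time:

* **Question A** — the current phase has lasted more timesteps than the
  model holds for it, by more than `multiplier ×` the phase-length std.
  Beyond the model's range there is no cell to score against, so the
  filter holds its last value and timing is the only evidence.
* **Question B** — the phase that just ended fell short of the model's
  step count by more than the same margin. The flag is held until the
  newly entered phase ends.
* **Question C** — independent of flags, the classifier tracks whether the
  most recently completed cycle was faster or slower than the training
  mean; this sign types a detected change as SU or SD. A change flagged
  before any cycle has completed (or on an exact tie) cannot be typed and
  yields NC with a `type-unresolvable` diagnostic.

Labels are per-frame and non-latching: a frame is SU/SD only while some
trigger is active, which matches per-timestep confusion-matrix scoring.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `squared_md_threshold` | 13.5 | — | χ²(4) CDF 0.99; balances delay vs false positives |
| `filter_cutoff` | 1.2 | Hz | ~1 cycle⁻¹: smooths within-cycle χ² noise, passes trial-scale shifts |
| `dt` | 0.01 | s | 100 Hz sensor rate |
| `timing_std_multiplier` | 1.0 | — | one-std margin on phase-timing mismatches |
| `ridge` λ | 1e-6 | deg² | regularizes near-singular cells (n ≤ m or noiseless data) |
| `min_cell_count` | 3 | — | cells below it are flagged; scoring proceeds with the ridge |
| `reference_phase` | LDS | — | cycle anchor for duration statistics |

## The synthetic generator

The generator emulates the statistical regime the algorithm assumes, not
musculoskeletal mechanics. Four channels are left/right thigh and shank
**elevation angles** (sagittal segment orientation relative to vertical,
degrees, positive forward). Each channel is a low-order Fourier series
(order 8) fitted to a time-warped cosine that peaks at that leg's heel
strike, falls monotonically through stance (62% of the cycle) and rises
through swing — which makes the virtual-leg angle trend usable for
stance/swing detection by construction. Amplitudes are 25° (thigh) and 35°
(shank); the right leg lags the left by half a cycle; phase fractions are
(0.12, 0.38, 0.12, 0.38) for (LDS, LSS, RDS, RSS), a typical
double-support share.

Speed dependence enters twice:

* amplitude: trajectories scale by `1 + g·(v − v_ref)` with `g = 0.4` per
  m/s — roughly a 12% excursion change for a 0.3 m/s speed change, a
  realistic excursion-vs-speed slope;
* timing: cycle duration follows `T(v) = T_ref (v_ref/v)^0.5` with
  `T_ref = 1.03 s` at `v_ref = 1.4 m/s` (cadence and step length both grow
  with speed, hence the square-root exponent).

Sensor noise is additive zero-mean Gaussian, 1° per channel by default
(full covariance configurable). The treadmill protocol ramps from
standstill to a 1.4 m/s baseline at 0.5 m/s² (a typical pedestrian
acceleration; configurable) and then runs nine speed-up and nine slow-down
trials — three each of 0.1, 0.2, 0.3 m/s, in that fixed order — with 15 s
dwells before and at each target speed.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: cycle-to-cycle timing variability (the
generator's timing is a deterministic function of the speed profile; real
gait has ~2–4% cycle-duration CV), baseline drift over a session (the
driver of false positives in real slow-down trials), left/right asymmetry,
soft-tissue and sensor artifacts, and any out-of-sagittal-plane motion.
Results on synthetic data characterize the algorithm under its own model
assumptions; they do not predict human-subject accuracy.

## Numerical choices and degenerate inputs

* **Covariance solves.** Cells are scored through a cached Cholesky
  factorization of `Σ + λI`; a numerically singular factor raises an
  error naming the (phase, k) cell.
* **Filter initialization.** The low-pass filter initializes at the first
  raw d², so a startup transient cannot cross the threshold spuriously.
* **Timing-std quantization floor.** Phase lengths are integers on the
  `dt` grid. At 100 Hz a 1.03 s cycle is exactly 103 frames, so phase
  boundaries sit on the grid knife-edge and clean constant-speed phase
  lengths wobble ±1 frame (std ≈ 0.45 steps). A sub-timestep std is grid
  aliasing, not gait variability, so Questions A/B floor the std at one
  timestep before applying the multiplier; otherwise a one-frame shortfall
  would flag a quarter of all steady-walking frames.
* **Cycle-duration ties.** Durations are computed as frame-count × dt in
  both training and classification, so identical cycles compare exactly
  equal in floating point; an exact tie in Question C resolves to
  "unchanged" (untypable).
* **Leading leg in double support** is the leg that most recently entered
  stance (a heel strike initiates double support). At stream start, an
  ambiguous opening is backfilled from the first resolvable event: the leg
  still in stance after the first toe-off led the opening double support.
* **Stance/swing from kinematics.** The signed sagittal virtual-leg angle
  is smoothed with a causal 5-frame moving average and a trend reversal
  must persist 3 frames before the state switches. Offline segmentation
  backdates each confirmed transition by the known confirmation lag plus
  the smoother's group delay, so phase boundaries line up with the true
  extrema; the contact-flag path (used by the real-time pipeline when
  available, and preferred when both are present) is strictly causal.
  The unsigned vertical angle is also provided, but it folds at vertical
  crossings; the signed variant is what is monotone through stance/swing.
* **k indexing** starts at 1 on the first frame of a phase; out-of-band
  frames are binned to the nearest dt grid cell.
* **Model fitting** drops the first phase run of a stream (a stream may
  start mid-phase with unknown offset) and uses only complete occurrences
  for timing statistics; with a single occurrence the std is stored as 0
  and the model flagged. Standing frames (zero belt speed) are excluded
  from training and classification.
* **Outlier rule.** Convergence and speed-probe means drop values beyond
  5 × IQR from the median, with quartiles computed by linear interpolation
  between order statistics — stated so the rule is bit-for-bit
  reproducible.
* **Ground truth** follows the literal speed-sign rule (faster than
  baseline = SU, slower = SD, equal = NC, with an optional tolerance
  band). During a return ramp this labels frames by the speed sign even
  though the user is heading back to baseline; users comparing against
  intent-at-the-person level should pass a tolerance.

## Design choices where the design was open

* Questions A and B compare against the model's **maximum** recorded step
  count per phase (the edge of the cell range), with the quantization
  floor above; Question B's flag persists until the phase it announced
  ends.
* Per-class accuracy is (TP+TN)/total from one-vs-rest counts; macro F1 is
  the unweighted mean of the three class F1 scores; 0/0 ratios are
  reported as 0 and flagged.
* Trials never correctly identified yield a missing delay, excluded from
  means with an explicit count.
* A detected change with an unresolved cycle direction is reported as NC
  rather than guessed.

## Problem sizes

The test suite and the acceptance script use a 300 s constant-speed
training set (~290 cycles; the convergence analysis refits on prefixes
from 10 to 300 s), a 120 s fresh scoring set, the full 18-trial protocol
(~570 s, ~57,000 frames), and 60 s probes at each of seven constant
speeds from −0.4 to +0.2 m/s around baseline. These match the modeled
experiment's scale; enlarging them changes the Monte-Carlo error, not the
behavior.

## Known limitations

* The model is per-user and per-speed-baseline; no drift adaptation or
  online re-baselining is provided.
* The distance cannot type a change by itself; typing relies on the cycle
  duration sign, so a change flagged mid-first-cycle is briefly untypable.
* The mean squared distance grows noticeably super-linearly with the
  speed offset on synthetic data (the Gaussian mean shift enters d²
  quadratically), so the per-side linear fits of the speed regression are
  a serviceable but imperfect summary (R² ≈ 0.9–0.95).
* Phase segmentation assumes the four-phase walking cycle; running (with
  flight phases) and non-cyclic movement are out of scope.
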