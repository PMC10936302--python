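# gaitintent

Real-time identification of walking-speed intent — **speed up (SU)**,
**slow down (SD)**, or **no change (NC)** — from multichannel kinematic
time series (e.g. joint angles from an IMU suit, exoskeleton encoders, or a
prosthesis), using only a few minutes of constant-speed training data.

The package is aimed at researchers in assistive robotics and human
movement analysis who need a data-efficient, sensor-agnostic intent signal:
pattern-recognition pipelines for the same task typically need hours of
per-user training data, which is infeasible in clinical settings where a
device may change users every hour.

## The model

Walking at constant intended speed is treated as a **cyclostationary
Gaussian process**. The gait cycle is split into four phases in fixed
cyclic order — left double support, left single support, right double
support, right single support (LDS → LSS → RDS → RSS) — and each timestep
`k` within phase `φ` gets its own multivariate Gaussian over the `m` sensor
channels:

```
x | (φ, k)  ~  N( μ_{φ,k}, Σ_{φ,k} )
```

Cells are assumed independent across timesteps; that simplification is what
lets the model converge with ~5 minutes of data. Each cell is trained with
single-pass recursive updates that reproduce the batch maximum-likelihood
(divide-by-n) mean and covariance exactly.

At run time every frame is scored with the **squared Mahalanobis distance**

```
d² = (x − μ_{φ,k})ᵀ (Σ_{φ,k} + λI)⁻¹ (x − μ_{φ,k})
```

which for in-distribution frames follows χ²(m). The signal is smoothed with
a causal first-order Butterworth low-pass (1.2 Hz) and compared with a
χ²-calibrated threshold: the default 13.5 sits at the 0.99 CDF level for
m = 4 channels. Two timing checks complement the distance test — the
current phase running *longer* than the model (Question A) or the previous
phase ending *shorter* than the model (Question B), each by more than one
training standard deviation of that phase's length. Any of the three
triggers flags a change of intent; its **type** comes from whether the most
recently completed gait cycle was faster (→ SU) or slower (→ SD) than the
training mean cycle (Question C). Unflagged frames are NC.

The package also ships a synthetic treadmill-walking generator (periodic
joint-angle templates with speed-dependent amplitude and cycle duration,
plus Gaussian sensor noise, under a standard 18-trial speed-change
protocol), gait-phase segmentation from foot contacts or from the
virtual-leg vector `2·(knee − hip) + (heel − knee)`, and the full
evaluation suite (confusion matrix, per-class metrics, detection delays,
threshold trade-off, convergence curve, distance-vs-speed regression).

## Worked example

```python
import gaitintent as gi

template = gi.default_template()
training = gi.simulate(template, gi.constant_speed_profile(1.4, 300.0), seed=0)
fitted = gi.CyclostationaryGaitModel.from_dataframe(training.frames).fit()
print(fitted.summary())

protocol = gi.build_standard_protocol()          # 9 speed-up + 9 slow-down trials
stream = gi.simulate(template, protocol, seed=1)
diagnostics = gi.run_stream(stream.frames, fitted)
report = gi.evaluate_protocol(stream, fitted, protocol.trials, diagnostics=diagnostics)
print(report.confusion.to_frame())
print(f"macro F1:   {report.metrics.macro_f1:.3f}")
print(f"mean delay: {report.mean_delay:.2f} s over {18 - report.n_missed_trials} identified trials")
```

prints

```
Cyclostationary gait model
==========================
channels (m):            4
sample interval dt:      0.01 s
ridge regularization:    1e-06 deg^2
training frames:         30000
training duration:       300.0 s
gait cycles observed:    290
cycle duration:          1.030 +/- 0.001 s

phase   cells  steps_mean  steps_std
LDS       13       12.71       0.45
LSS       39       39.00       0.00
RDS       12       12.00       0.00
RSS       40       39.29       0.45

       U      D      N
U  11507    216   2495
D      0  11238   3258
N     60     91  28355
macro F1:   0.887
mean delay: 0.57 s over 18 identified trials
```

The summary shows the fitted model: one Gaussian cell per (phase, timestep)
— e.g. 39 cells spanning left single support — and a 1.03 s mean training
cycle. On the 18-trial protocol the classifier labels every 10 ms frame;
the confusion matrix compares those labels with the speed-derived ground
truth (rows = truth SU/SD/NC, columns = estimate), and the mean delay is
the time from each speed-change onset to the first correctly typed label —
here well under one gait cycle.

The same pipeline is available from the shell:

```
gaitintent simulate --seed 0 --constant-speed 1.4 --duration 300 --out train.csv
gaitintent train train.csv --out model.json
gaitintent simulate --seed 1 --out protocol.csv
gaitintent run protocol.csv --model model.json --out diagnostics.csv
gaitintent sweep protocol.csv --model model.json --out tradeoff.csv
gaitintent converge train.csv --out convergence.csv
```

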