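# Methods

This note records the model equations, default parameters and the rationale
behind the non-obvious choices. All signals are uniformly sampled at
`fs = 200 Hz` unless stated otherwise.

## Whisking drives

* **Periodic**: `u(t) = A sin(2 pi f t)` with `f = 3 Hz`, `A = 1`.
* **Stochastic**: Gaussian white noise through a causal 4th-order Butterworth
  band-pass (2–4 Hz), rescaled to a target standard deviation. In the
  scenario experiments the default standard deviation is **0.5**, so typical
  (2-sigma) excursions match the periodic drive's +/-1 range. This keeps the
  motor command inside the bilinear plant's stability envelope (see below)
  and makes the two whisking modes energetically comparable.
* **Sawtooth** (`make_whisk_sawtooth`): a +/-1 square wave at the whisking
  frequency (40 % duty cycle by default) through a first-order low-pass,
  `y[n] = a y[n-1] + (1-a) u[n]`, `a = exp(-1/(fs tau))`, `tau = 60 ms` —
  an asymmetric protraction/retraction profile. As `tau -> 0` the output
  reduces exactly to the square wave.

## Plant

The reafferent deflection `r` follows a second-order difference equation
with an optional bilinear input-state cross-product:

```
r[t] = -a1 r[t-1] - a2 r[t-2] + b1 u[t-1] + b2 u[t-2] + k u[t-1] r[t-1]
```

`k = 0` is the purely linear plant; `k` is swept over `[0, 0.05]`.

**Default linear coefficients** are the zero-order-hold discretization of a
continuous second-order low-pass with natural frequency `fn = 15 Hz`,
damping ratio `zeta = 0.8` and unit DC gain. Rationale: the bilinear term
effectively perturbs the first feedback coefficient by `k u[t-1]`, so the
recursion stays stable only while `|k u|` remains inside the discrete-pole
margin `1 + a2 - |a1|`. The chosen discretization has margin ~0.153, which
comfortably covers `k = 0.05` at whisking-scale inputs (`|u| <= 1`); a
regression test drives the `k = 0.05` plant for 1000 s at full amplitude and
requires that the divergence guard never fires. Much slower or more lightly
damped second-order plants have margins of order 0.01 and blow up within
seconds under the same sweep, which would make the nonlinearity comparison
meaningless. In the whisking band (2–4 Hz) the default plant has near-unit
gain, so the reafference is a gently filtered copy of the drive.

`simulate_reafferent` guards against bilinear divergence: if `|r|` exceeds
1000x the RMS of the linear (`k = 0`) response, it raises
`SimulationDivergedError` with the offending sample index.

## Contacts

Contact onsets are Bernoulli draws: one uniform draw per sample, a contact
whenever the draw exceeds `theta = 0.999` (~0.2 contacts/s at 200 Hz). Each
contact adds a damped-cosine transient

```
h(t) = A_c cos(2 pi 15 t) exp(-t / 0.05),   0 <= t < 0.2 s
```

with peak amplitude `A_c = 3 x RMS(r)` of that trial's reafferent signal,
i.e. contact amplitude is yoked to whisk vigour. Overlapping transients add
linearly; transients are truncated at the record end.

White Gaussian **sensor noise** with standard deviation 0.03 (a
reafference-to-noise floor of roughly 27 dB at the default drive scale) is
added to the observed signal `z = r + x + n`. Every physical deflection
sensor has such a floor; without one, the comparison between filter schemes
degenerates into a measurement of each scheme's own LMS adaptation noise
(excess mean-square error), which is not the quantity of interest.

## Adaptive filter

Each enabled input line feeds a tap-delay line of **100 taps at 5 ms
spacing** (0.5 s of history per input). Every input line carries a **10 ms
processing delay**; the sensory line carries an additional **100 ms
decorrelation delay** so its taps cannot see (and therefore cannot cancel)
the first half of an ongoing contact transient.

Per sample:

```
p[t]    = concatenated delayed taps (motor first)
y_hat[t] = w . p[t]
e[t]    = z[t] - y_hat[t]          # the novelty signal
w      <- w + beta * e[t] * p[t]   # LMS update
```

Weights start at zero; `beta = 5e-4` by default ("slow" rate; the
mean-square-stability bound scales as `2 / (beta * tr R)`, and this value
sits well inside it for all grid scenarios). A non-finite `e` raises
`UpdateDivergedError`. Two implementations share the arithmetic: a readable
per-sample `AdaptiveFilter` class and a numba-compiled batch loop
(`run_novelty_scheme`); a test pins their equivalence.

With `beta = 0` the filter passes `z` through bit-exactly, which together
with `initial_weights` supports frozen-weight replays.

## SNR protocol

For a signal `s` and a contact schedule:

* **signal region** — the union of 200 ms windows after each contact onset
  (overlaps unioned, end-of-record windows truncated);
* **noise region** — all other samples;
* both restricted to `t >= eval_start`, chosen after filter convergence
  (final 200 s of full-length 1000 s runs; final 20 % of shorter runs);
* `SNR = 10 log10(var_signal / var_noise)` (population variance, ddof 0);
* **improvement** = scheme-output SNR minus raw-sensory SNR, in dB.

The ratio is invariant under rescaling of `s`, so schemes that merely change
overall gain score zero improvement.

## Scenario grid

`run_scenario_grid` sweeps {stochastic, periodic} x `k` x {sensory, motor,
sensorimotor}, `n_trials` seeded trials per cell. Per-trial seeding uses
`SeedSequence([base_seed, trial])` to derive three independent streams
(drive, contacts, sensor noise), masked below 2^31. Seeds depend only on the
trial index, so drives and contact schedules are **matched across cells**:
scheme and `k` comparisons are paired, not independent. One simulation per
trial is shared by all schemes. A diverged trial is logged and dropped; the
grid fails loudly if more than 10 % of trials diverge.

Defaults mirror the full experiment (1000 s, 20 trials); the test battery
runs a scaled version (400 s, 10 trials, `k` in {0, 0.025, 0.05}).

## Identification and inference

* `identify_linear_plant`: ARX least squares on lagged outputs/inputs,
  minimizing one-step-ahead prediction error; raises on regressor condition
  numbers above 1e10 (unexciting inputs). Recovers noise-free plant
  coefficients to better than 1e-6.
* `infer_contact_response`: the mean of `z - r_pred` over post-contact
  windows — the contact transient is never measured directly, only inferred
  from prediction residuals; averaging over contacts suppresses prediction
  noise roughly as `1/sqrt(n_contacts)`.

## Determinism

Every random element is seeded (`numpy` `default_rng` / `SeedSequence`);
the numba kernels are compiled with `cache=True` and contain purely
sequential scalar arithmetic, so all outputs — including the spectral
targets and the full grid tables — are bit-reproducible across runs and
machines with the same dependency versions.
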