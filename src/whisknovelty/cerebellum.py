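"""Adaptive-filter model of the cerebellar microcircuit.

The filter performs analysis by tap-delay lines (the parallel-fibre analogue:
each enabled input is exposed at a bank of fixed lags), synthesis by a weight
vector (parallel fibre–Purkinje cell synapses), and correlational LMS weight
adaptation driven by the comparator output.  The novelty signal is

    e(t) = z(t) - y_hat(t)

where z is the observed sensory signal and y_hat the filter's prediction of
its reafferent component.  Three wirings are supported:

* ``motor`` — a copy of the motor command feeds the taps (forward model);
* ``sensory`` — the sensory signal's own delayed past feeds the taps (signal
  model); an extra decorrelation delay keeps the filter from cancelling the
  contact transients themselves;
* ``sensorimotor`` — both lines, concatenated.

The weight update ``w_i <- w_i + beta * p_i * e`` is the standard LMS rule;
in the biological convention the climbing fibre carries ``-e`` and positive
correlation depresses the synapse — the net weight change is identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import lms_run
from .signals import TimeSeries

__all__ = [
    "AdaptiveFilterConfig",
    "AdaptiveFilter",
    "NoveltyResult",
    "UpdateDivergedError",
    "run_novelty_scheme",
]

MODES = ("motor", "sensory", "sensorimotor")


class UpdateDivergedError(RuntimeError):
    """The weight update produced a non-finite error signal."""


@dataclass(frozen=True)
class AdaptiveFilterConfig:
    """Filter wiring and adaptation parameters.

    Defaults follow the simulated-experiment settings: 100 taps per input at
    5 ms spacing, slow learning rate 5e-4, 10 ms processing delay on every
    input line, and a 100 ms decorrelation delay on the sensory line.
    """

    mode: str = "motor"
    n_taps_per_input: int = 100
    tap_spacing_s: float = 0.005
    learning_rate: float = 5e-4
    processing_delay_s: float = 0.010
    sensory_decorrelation_delay_s: float = 0.100

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_taps_per_input < 1:
            raise ValueError("n_taps_per_input must be >= 1")
        if self.tap_spacing_s <= 0:
            raise ValueError("tap_spacing_s must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.processing_delay_s < 0 or self.sensory_decorrelation_delay_s < 0:
            raise ValueError("delays must be non-negative")

    @property
    def uses_motor(self) -> bool:
        return self.mode in ("motor", "sensorimotor")

    @property
    def uses_sensory(self) -> bool:
        return self.mode in ("sensory", "sensorimotor")

    @property
    def n_inputs(self) -> int:
        return 2 if self.mode == "sensorimotor" else 1

    @property
    def total_taps(self) -> int:
        return self.n_taps_per_input * self.n_inputs

    def _samples(self, seconds: float, sample_rate_hz: float, what: str) -> int:
        exact = seconds * sample_rate_hz
        n = int(round(exact))
        if abs(exact - n) > 1e-6:
            raise ValueError(
                f"{what} ({seconds} s) is not an integer number of samples "
                f"at {sample_rate_hz} Hz"
            )
        return n

    def tap_stride(self, sample_rate_hz: float) -> int:
        n = self._samples(self.tap_spacing_s, sample_rate_hz, "tap spacing")
        if n < 1:
            raise ValueError("tap spacing must be at least one sample")
        return n

    def motor_delay_samples(self, sample_rate_hz: float) -> int:
        return self._samples(self.processing_delay_s, sample_rate_hz, "processing delay")

    def sensory_delay_samples(self, sample_rate_hz: float) -> int:
        return self.motor_delay_samples(sample_rate_hz) + self._samples(
            self.sensory_decorrelation_delay_s, sample_rate_hz, "decorrelation delay"
        )


class AdaptiveFilter:
    """Online per-sample state: tap buffers plus the weight vector.

    This is the readable, sample-at-a-time implementation of the scheme;
    :func:`run_novelty_scheme` drives the same arithmetic through a compiled
    loop for long records.
    """

    def __init__(self, config: AdaptiveFilterConfig, sample_rate_hz: float):
        self.config = config
        self.sample_rate_hz = float(sample_rate_hz)
        self.stride = config.tap_stride(sample_rate_hz)
        self.d_motor = config.motor_delay_samples(sample_rate_hz)
        self.d_sensory = config.sensory_delay_samples(sample_rate_hz)
        span = (config.n_taps_per_input - 1) * self.stride
        self._ubuf = np.zeros(self.d_motor + span + 1)
        self._zbuf = np.zeros(self.d_sensory + span + 1)
        self.weights = np.zeros(config.total_taps)

    def assemble_components(self, u_t: float, z_t: float) -> np.ndarray:
        """Advance the buffers by one sample and return the component vector p.

        ``p`` concatenates, per enabled input line, the delayed samples at the
        configured lags (motor taps first).  Buffers start zero-filled.
        """
        self._ubuf[1:] = self._ubuf[:-1]
        self._ubuf[0] = u_t
        self._zbuf[1:] = self._zbuf[:-1]
        self._zbuf[0] = z_t
        cfg = self.config
        idx = np.arange(cfg.n_taps_per_input) * self.stride
        parts = []
        if cfg.uses_motor:
            parts.append(self._ubuf[self.d_motor + idx])
        if cfg.uses_sensory:
            parts.append(self._zbuf[self.d_sensory + idx])
        return np.concatenate(parts)

    def predict(self, p: np.ndarray) -> float:
        """Filter output y_hat = w . p; no side effects."""
        if p.shape != self.weights.shape:
            raise ValueError(
                f"component vector length {p.size} != weight count {self.weights.size}"
            )
        return float(self.weights @ p)

    def lms_update(self, p: np.ndarray, e_t: float) -> None:
        """LMS step: w <- w + beta * p * e."""
        if not np.isfinite(e_t):
            raise UpdateDivergedError("non-finite error signal in weight update")
        self.weights += self.config.learning_rate * e_t * p

    def step(self, u_t: float, z_t: float) -> tuple[float, float]:
        """One full cycle: assemble, predict, compare, adapt.

        Returns ``(e_t, y_hat_t)``.
        """
        p = self.assemble_components(u_t, z_t)
        y_hat = self.predict(p)
        e_t = z_t - y_hat
        self.lms_update(p, e_t)
        return e_t, y_hat


@dataclass(frozen=True)
class NoveltyResult:
    """Output of a novelty-scheme run."""

    e: TimeSeries
    y_hat: TimeSeries
    weights: np.ndarray
    weight_snapshots: np.ndarray  # (n_snapshots, total_taps)
    snapshot_times_s: np.ndarray
    config: AdaptiveFilterConfig


def run_novelty_scheme(
    u: TimeSeries,
    z: TimeSeries,
    config: AdaptiveFilterConfig,
    initial_weights: np.ndarray | None = None,
    snapshot_interval_s: float = 10.0,
) -> NoveltyResult:
    """Run the full online scheme over aligned motor and sensory records.

    Per sample: assemble the component vector, predict y_hat, emit
    ``e = z - y_hat``, apply the LMS update.  Deterministic given inputs.
    Weights start at zero unless ``initial_weights`` is given (pass the final
    weights of a previous run with ``learning_rate = 0`` for a frozen replay).
    """
    if len(u) != len(z):
        raise ValueError(f"length mismatch: u has {len(u)}, z has {len(z)} samples")
    if abs(u.sample_rate_hz - z.sample_rate_hz) > 1e-9:
        raise ValueError("sample rate mismatch between u and z")
    fs = z.sample_rate_hz
    stride = config.tap_stride(fs)
    d_m = config.motor_delay_samples(fs)
    d_s = config.sensory_delay_samples(fs)
    n_taps = config.n_taps_per_input
    span = (n_taps - 1) * stride
    pad = max(d_m, d_s) + span

    if initial_weights is None:
        w = np.zeros(config.total_taps)
    else:
        w = np.array(initial_weights, dtype=np.float64)
        if w.shape != (config.total_taps,):
            raise ValueError("initial_weights has wrong length for this config")

    u_pad = np.concatenate([np.zeros(pad), u.values])
    z_pad = np.concatenate([np.zeros(pad), z.values])

    snap_every = max(1, int(round(snapshot_interval_s * fs)))
    n_snaps = len(z) // snap_every
    snaps = np.zeros((n_snaps, config.total_taps))

    e_vals, y_vals, bad = lms_run(
        u_pad,
        z_pad,
        z.values,
        w,
        n_taps,
        stride,
        config.uses_motor,
        config.uses_sensory,
        pad - d_m,
        pad - d_s,
        config.learning_rate,
        snap_every,
        snaps,
    )
    if bad >= 0:
        raise UpdateDivergedError(
            f"non-finite error signal at sample {bad} (t = {bad / fs:.3f} s); "
            "learning rate likely exceeds the stability bound"
        )
    snap_times = (np.arange(n_snaps) + 1) * snap_every / fs
    return NoveltyResult(
        e=z.with_values(e_vals),
        y_hat=z.with_values(y_vals),
        weights=w,
        weight_snapshots=snaps,
        snapshot_times_s=snap_times,
        config=config,
    )
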