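"""The simulated whisking plant.

Motor commands drive a second-order discrete-time linear system (optionally
with a bilinear input-state cross-product) whose output is the reafferent
signal — the sensor deflection caused by the whisker's own motion.  Contacts
with external objects arrive at Bernoulli-scheduled times and are rendered
through a finite impulse response into the exafferent signal.  The observed
sensory signal is their sum.  The module also identifies a linear plant from
input–output records (ARX least squares) and infers the contact response from
prediction residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._kernels import bilinear_recursion
from .signals import TimeSeries

__all__ = [
    "LinearPlantParams",
    "BilinearPlant",
    "ContactResponse",
    "ContactSchedule",
    "ARXFit",
    "SimulationDivergedError",
    "IllConditionedIdentificationError",
    "NoContactsError",
    "default_plant",
    "make_contact_response",
    "simulate_reafferent",
    "generate_contact_schedule",
    "render_exafferent",
    "compose_sensory",
    "identify_linear_plant",
    "infer_contact_response",
]


class SimulationDivergedError(RuntimeError):
    """The plant recursion exceeded its divergence guard."""


class IllConditionedIdentificationError(RuntimeError):
    """The identification regressor is (numerically) rank deficient."""


class NoContactsError(ValueError):
    """An operation requiring contacts was given an empty schedule."""


@dataclass(frozen=True)
class LinearPlantParams:
    """Coefficients of the second-order transfer function
    ``(b1 q^-1 + b2 q^-2) / (1 + a1 q^-1 + a2 q^-2)``."""

    a1: float
    a2: float
    b1: float
    b2: float
    sample_rate_hz: float

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "b1", "b2", "sample_rate_hz"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        poles = np.roots([1.0, self.a1, self.a2])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                f"unstable plant: pole magnitudes {np.abs(poles)} not all < 1"
            )

    @property
    def poles(self) -> np.ndarray:
        return np.roots([1.0, self.a1, self.a2])


@dataclass(frozen=True)
class BilinearPlant:
    """Linear plant plus bilinear coefficient ``k`` (cross-product of the
    lagged motor input and lagged reafferent output; k = 0 is purely linear)."""

    linear: LinearPlantParams
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0 or not np.isfinite(self.k):
            raise ValueError("k must be finite and >= 0")

    @property
    def sample_rate_hz(self) -> float:
        return self.linear.sample_rate_hz


@dataclass(frozen=True)
class ContactResponse:
    """Finite impulse response rendering one contact into a sensory transient."""

    h: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=np.float64)
        if h.ndim != 1 or h.size < 1:
            raise ValueError("impulse response must be 1-D with length >= 1")
        if not np.all(np.isfinite(h)):
            raise ValueError("impulse response values must be finite")
        h.setflags(write=False)
        object.__setattr__(self, "h", h)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


@dataclass(frozen=True)
class ContactSchedule:
    """Sample indices of contact onsets drawn by a Bernoulli process."""

    times: np.ndarray
    threshold: float
    duration_s: float
    sample_rate_hz: float
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        n = int(round(self.duration_s * self.sample_rate_hz))
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("contact indices must be strictly increasing")
            if times[0] < 0 or times[-1] >= n:
                raise ValueError("contact indices must lie within the record")
        times.setflags(write=False)
        object.__setattr__(self, "times", times)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    @property
    def times_s(self) -> np.ndarray:
        return self.times / self.sample_rate_hz

    def __len__(self) -> int:
        return self.times.size


def default_plant(sample_rate_hz: float = 200.0, k: float = 0.0) -> BilinearPlant:
    """The default whisking plant: a compliant second-order carrier.

    Zero-order-hold discretization of a continuous second-order system with
    natural frequency 15 Hz, damping ratio 0.8 and unit DC gain: near-unit
    gain across the 2–4 Hz whisking band with a gentle roll-off above.  The
    damping is chosen so that the bilinear cross-product term — which
    perturbs the first feedback coefficient by k*u — stays well inside the
    discrete pole margin 1 + a2 - |a1| (~0.15 here) over the whole tested
    range (k up to 0.05 at whisking-scale inputs), keeping both the plant
    recursion and the downstream LMS adaptation stable.
    """
    wn = 2 * np.pi * 15.0
    zeta = 0.8
    num = [wn**2]
    den = [1.0, 2 * zeta * wn, wn**2]
    (bz, az, _) = sps.cont2discrete((num, den), dt=1.0 / sample_rate_hz, method="zoh")
    bz = np.atleast_1d(np.squeeze(bz))
    az = np.atleast_1d(np.squeeze(az))
    # strictly proper: bz = [~0, b1, b2], az = [1, a1, a2]
    linear = LinearPlantParams(
        a1=float(az[1]),
        a2=float(az[2]),
        b1=float(bz[1]),
        b2=float(bz[2]),
        sample_rate_hz=sample_rate_hz,
    )
    return BilinearPlant(linear=linear, k=k)


def make_contact_response(
    peak_amplitude: float = 1.0,
    freq_hz: float = 15.0,
    decay_tau_s: float = 0.05,
    duration_s: float = 0.2,
    sample_rate_hz: float = 200.0,
) -> ContactResponse:
    """Damped-cosine contact transient (struck-cantilever-like ringing).

    ``h(t) = peak_amplitude * cos(2*pi*freq_hz*t) * exp(-t/decay_tau_s)`` over
    ``duration_s``.  Defaults: 15 Hz ringing, 50 ms decay, 200 ms long.
    """
    n = int(round(duration_s * sample_rate_hz))
    if n < 1:
        raise ValueError("duration too short for one sample")
    t = np.arange(n) / sample_rate_hz
    h = peak_amplitude * np.cos(2 * np.pi * freq_hz * t) * np.exp(-t / decay_tau_s)
    return ContactResponse(h, sample_rate_hz)


def simulate_reafferent(plant: BilinearPlant, u: TimeSeries) -> TimeSeries:
    """Reafferent response to motor command ``u``, zero initial conditions.

    ``r[t] = -a1*r[t-1] - a2*r[t-2] + b1*u[t-1] + b2*u[t-2] + k*u[t-1]*r[t-1]``.
    With ``k = 0`` this is exactly the linear difference equation.

    Raises
    ------
    SimulationDivergedError
        If |r| exceeds 1000x the RMS of the linear (k = 0) response — the
        bilinear feedback can destabilize the loop for large inputs.
    """
    lp = plant.linear
    if abs(u.sample_rate_hz - lp.sample_rate_hz) > 1e-9:
        raise ValueError(
            f"rate mismatch: input {u.sample_rate_hz} Hz, plant {lp.sample_rate_hz} Hz"
        )
    b = [0.0, lp.b1, lp.b2]
    a = [1.0, lp.a1, lp.a2]
    rms_lin = float(np.sqrt(np.mean(sps.lfilter(b, a, u.values) ** 2)))
    guard = 1e3 * rms_lin if rms_lin > 0 else np.inf
    r, bad = bilinear_recursion(
        u.values, lp.a1, lp.a2, lp.b1, lp.b2, plant.k, guard
    )
    if bad >= 0:
        raise SimulationDivergedError(
            f"plant output exceeded divergence guard at sample {bad} "
            f"(t = {bad / lp.sample_rate_hz:.3f} s, k = {plant.k})"
        )
    return u.with_values(r)


def generate_contact_schedule(
    duration_s: float,
    sample_rate_hz: float = 200.0,
    threshold: float = 0.999,
    seed: int = 0,
) -> ContactSchedule:
    """Bernoulli contact onsets: one uniform draw per sample, contact iff the
    draw exceeds ``threshold`` (default 0.999, i.e. ~0.2 contacts/s at 200 Hz)."""
    if not (0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    n = int(round(duration_s * sample_rate_hz))
    if n < 1:
        raise ValueError("duration too short for one sample")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 1.0, size=n)
    times = np.nonzero(draws > threshold)[0]
    return ContactSchedule(
        times=times,
        threshold=threshold,
        duration_s=duration_s,
        sample_rate_hz=sample_rate_hz,
        seed=seed,
    )


def render_exafferent(
    schedule: ContactSchedule, response: ContactResponse, n_samples: int
) -> TimeSeries:
    """Exafferent signal: superposed copies of the contact response, one per
    scheduled onset, truncated at ``n_samples``.  Overlaps add linearly."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if abs(schedule.sample_rate_hz - response.sample_rate_hz) > 1e-9:
        raise ValueError("schedule and response sample rates differ")
    x = np.zeros(n_samples)
    h = response.h
    for c in schedule.times:
        if c >= n_samples:
            break
        stop = min(c + h.size, n_samples)
        x[c:stop] += h[: stop - c]
    return TimeSeries(x, schedule.sample_rate_hz)


def compose_sensory(r: TimeSeries, x: TimeSeries) -> TimeSeries:
    """Observed sensory signal z = r + x (reafferent plus exafferent)."""
    if len(r) != len(x):
        raise ValueError(f"length mismatch: {len(r)} vs {len(x)}")
    if abs(r.sample_rate_hz - x.sample_rate_hz) > 1e-9:
        raise ValueError("sample rate mismatch")
    return r.with_values(r.values + x.values)


@dataclass(frozen=True)
class ARXFit:
    """Result of least-squares ARX identification."""

    a: np.ndarray  # (a1 .. a_na)
    b: np.ndarray  # (b1 .. b_nb)
    residual_variance: float
    condition_number: float
    sample_rate_hz: float

    @property
    def params(self) -> LinearPlantParams:
        if self.a.size != 2 or self.b.size != 2:
            raise ValueError("params property requires a 2/2-order fit")
        return LinearPlantParams(
            a1=float(self.a[0]),
            a2=float(self.a[1]),
            b1=float(self.b[0]),
            b2=float(self.b[1]),
            sample_rate_hz=self.sample_rate_hz,
        )


def identify_linear_plant(
    u: TimeSeries,
    r: TimeSeries,
    order_a: int = 2,
    order_b: int = 2,
    cond_limit: float = 1e10,
) -> ARXFit:
    """Fit an ARX model by ordinary least squares on lagged outputs and inputs.

    Minimizes the one-step-ahead squared prediction error of
    ``r[t] = -sum_i a_i r[t-i] + sum_j b_j u[t-j]``.

    Raises
    ------
    IllConditionedIdentificationError
        If the regressor condition number exceeds ``cond_limit`` (e.g. for a
        constant, unexciting input).
    """
    if len(u) != len(r):
        raise ValueError("input and output lengths differ")
    if abs(u.sample_rate_hz - r.sample_rate_hz) > 1e-9:
        raise ValueError("sample rate mismatch")
    p = max(order_a, order_b)
    n = len(r)
    if n <= p + order_a + order_b:
        raise ValueError("record too short for the requested model orders")
    y = r.values[p:]
    cols = [-r.values[p - i : n - i] for i in range(1, order_a + 1)]
    cols += [u.values[p - j : n - j] for j in range(1, order_b + 1)]
    phi = np.column_stack(cols)
    cond = float(np.linalg.cond(phi))
    if not np.isfinite(cond) or cond > cond_limit:
        raise IllConditionedIdentificationError(
            f"regressor condition number {cond:.3g} exceeds {cond_limit:.3g}; "
            "input does not excite the system"
        )
    theta, _, _, _ = np.linalg.lstsq(phi, y, rcond=None)
    resid = y - phi @ theta
    return ARXFit(
        a=theta[:order_a].copy(),
        b=theta[order_a:].copy(),
        residual_variance=float(np.var(resid)),
        condition_number=cond,
        sample_rate_hz=u.sample_rate_hz,
    )


def infer_contact_response(
    z: TimeSeries,
    r_pred: TimeSeries,
    schedule: ContactSchedule,
    length_samples: int,
) -> ContactResponse:
    """Infer the contact transient as the mean of ``z - r_pred`` over
    post-contact windows (the contact response is never measured directly)."""
    if len(z) != len(r_pred):
        raise ValueError("length mismatch between z and r_pred")
    if len(schedule) == 0:
        raise NoContactsError("schedule contains no contacts")
    if length_samples < 1:
        raise ValueError("length_samples must be >= 1")
    diff = z.values - r_pred.values
    windows = []
    for c in schedule.times:
        if c + length_samples > len(z):
            continue
        windows.append(diff[c : c + length_samples])
    if not windows:
        raise NoContactsError("no contact window fits within the record")
    h = np.mean(np.stack(windows), axis=0)
    return ContactResponse(h, z.sample_rate_hz)
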