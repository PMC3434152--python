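"""Uniformly sampled time series: whisking drives, noise inputs, and file I/O.

Every signal in the package — motor commands, reafferent and exafferent
components, the observed sensory signal, filter predictions and novelty
outputs — is carried by the same :class:`TimeSeries` container.  The working
sample rate throughout is 200 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "TimeSeriesFormatError",
    "make_sine",
    "make_whisk_sawtooth",
    "make_bandpass_noise",
    "lowpass_downsample",
    "periodogram_peaks",
    "read_timeseries",
    "write_timeseries",
]


class TimeSeriesFormatError(ValueError):
    """Raised when a time-series file does not conform to the expected dialect."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : ndarray
        Sample values; must be finite and at least one sample long.
    sample_rate_hz : float
        Sampling rate, strictly positive.
    t0_s : float
        Time of the first sample; sample ``i`` occurs at ``t0_s + i / rate``.
    """

    values: np.ndarray
    sample_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("TimeSeries requires a 1-D array with >= 1 sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.sample_rate_hz > 0) or not np.isfinite(self.sample_rate_hz):
            raise ValueError("sample_rate_hz must be positive and finite")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_rate_hz", float(self.sample_rate_hz))
        object.__setattr__(self, "t0_s", float(self.t0_s))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.sample_rate_hz

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """New series with the same clock but different values."""
        return TimeSeries(values, self.sample_rate_hz, self.t0_s)


def _check_rate_duration(duration_s: float, sample_rate_hz: float) -> int:
    if not (duration_s > 0):
        raise ValueError("duration_s must be positive")
    if not (sample_rate_hz > 0):
        raise ValueError("sample_rate_hz must be positive")
    n = int(round(duration_s * sample_rate_hz))
    if n < 1:
        raise ValueError("duration too short for one sample at this rate")
    return n


def make_sine(
    freq_hz: float,
    amplitude: float = 1.0,
    duration_s: float = 1.0,
    sample_rate_hz: float = 200.0,
    phase_rad: float = 0.0,
) -> TimeSeries:
    """Sinusoidal drive, the periodic whisking input (default use: 3 Hz).

    ``values[i] = amplitude * sin(2*pi*freq_hz*i/rate + phase_rad)``.
    """
    n = _check_rate_duration(duration_s, sample_rate_hz)
    if not (freq_hz > 0):
        raise ValueError("freq_hz must be positive")
    if freq_hz >= sample_rate_hz / 2:
        raise ValueError("freq_hz must be below the Nyquist rate")
    i = np.arange(n)
    values = amplitude * np.sin(2 * np.pi * freq_hz * i / sample_rate_hz + phase_rad)
    return TimeSeries(values, sample_rate_hz)


def make_whisk_sawtooth(
    freq_hz: float = 3.0,
    duty_fraction: float = 0.4,
    tau_s: float = 0.06,
    duration_s: float = 10.0,
    sample_rate_hz: float = 200.0,
) -> TimeSeries:
    """Sawtooth-like whisking drive: low-passed square wave.

    A zero-mean square wave (levels +/-1, high for ``duty_fraction`` of each
    cycle) passed through a first-order low-pass with time constant ``tau_s``,
    emulating the fast/slow protraction–retraction phases of rat whisking.
    Defaults: 3 Hz, 40 % duty cycle, 60 ms time constant.
    """
    n = _check_rate_duration(duration_s, sample_rate_hz)
    if not (0.0 < duty_fraction < 1.0):
        raise ValueError("duty_fraction must lie strictly inside (0, 1)")
    if not (tau_s > 0):
        raise ValueError("tau_s must be positive")
    if freq_hz >= sample_rate_hz / 2:
        raise ValueError("freq_hz must be below the Nyquist rate")
    i = np.arange(n)
    cycle_pos = (i * freq_hz / sample_rate_hz) % 1.0
    square = np.where(cycle_pos < duty_fraction, 1.0, -1.0)
    # first-order low-pass, exact for input held constant over each interval:
    # y[n] = a*y[n-1] + (1-a)*u[n], a = exp(-dt/tau); zero initial state
    a = float(np.exp(-1.0 / (sample_rate_hz * tau_s)))
    values = sps.lfilter([1.0 - a], [1.0, -a], square)
    return TimeSeries(values, sample_rate_hz)


def make_bandpass_noise(
    low_hz: float = 2.0,
    high_hz: float = 4.0,
    duration_s: float = 10.0,
    sample_rate_hz: float = 200.0,
    seed: int = 0,
) -> TimeSeries:
    """Stochastic whisking drive: band-pass filtered Gaussian white noise.

    Unit-variance Gaussian noise through a causal 4th-order Butterworth
    band-pass (default pass-band 2–4 Hz), then rescaled to unit sample
    variance.  Deterministic for a given seed.
    """
    n = _check_rate_duration(duration_s, sample_rate_hz)
    if not (0 < low_hz < high_hz < sample_rate_hz / 2):
        raise ValueError("require 0 < low_hz < high_hz < Nyquist")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    b, a = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=sample_rate_hz)
    filtered = sps.lfilter(b, a, white)
    std = float(np.std(filtered))
    if std == 0.0:
        raise ValueError("degenerate noise realization (zero variance)")
    return TimeSeries(filtered / std, sample_rate_hz)


def lowpass_downsample(
    ts: TimeSeries, cutoff_hz: float, target_rate_hz: float
) -> TimeSeries:
    """Anti-alias low-pass then integer decimation (e.g. 2 kHz -> 200 Hz at 10 Hz).

    The low-pass is a causal 4th-order Butterworth whose initial state is
    matched to the first sample, so a constant signal passes through unchanged.
    """
    factor = ts.sample_rate_hz / target_rate_hz
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ValueError(
            f"target rate {target_rate_hz} Hz must divide the input rate "
            f"{ts.sample_rate_hz} Hz (integer decimation)"
        )
    if not (0 < cutoff_hz < target_rate_hz / 2):
        raise ValueError("cutoff_hz must be below the target Nyquist rate")
    b, a = sps.butter(4, cutoff_hz, btype="lowpass", fs=ts.sample_rate_hz)
    zi = sps.lfilter_zi(b, a) * ts.values[0]
    filtered, _ = sps.lfilter(b, a, ts.values, zi=zi)
    decimated = filtered[:: int(round(factor))]
    return TimeSeries(decimated, target_rate_hz, ts.t0_s)


def periodogram_peaks(
    ts: TimeSeries, rel_threshold: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Locate spectral peaks: local maxima of the plain periodogram whose
    power exceeds ``rel_threshold`` times the strongest peak's power.

    Returns (frequencies_hz, powers), sorted by frequency.  Used to read off
    a drive fundamental and any harmonics introduced by plant nonlinearity.
    """
    from scipy.signal import find_peaks

    if not (0 < rel_threshold <= 1):
        raise ValueError("rel_threshold must lie in (0, 1]")
    freqs, power = sps.periodogram(ts.values, fs=ts.sample_rate_hz)
    idx, _ = find_peaks(power, height=rel_threshold * float(np.max(power)))
    return freqs[idx], power[idx]


def write_timeseries(ts: TimeSeries, path) -> None:
    """Write a series as delimited text: two commented header lines then one
    value per row, full double precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_rate_hz={ts.sample_rate_hz!r}\n")
        fh.write(f"# t0_s={ts.t0_s!r}\n")
        for v in ts.values:
            fh.write(f"{float(v)!r}\n")


def _parse_header_line(line: str, key: str, lineno: int) -> float:
    stripped = line.strip()
    prefix = f"# {key}="
    if not stripped.startswith("#"):
        raise TimeSeriesFormatError(f"line {lineno}: expected header '# {key}=<float>'")
    body = stripped.lstrip("#").strip()
    if not body.startswith(f"{key}="):
        raise TimeSeriesFormatError(
            f"line {lineno}: expected header field '{key}', got {stripped!r}"
        )
    try:
        return float(body.split("=", 1)[1])
    except ValueError as exc:
        raise TimeSeriesFormatError(
            f"line {lineno}: non-numeric value in header field '{key}'"
        ) from exc


def read_timeseries(path) -> TimeSeries:
    """Read the delimited dialect written by :func:`write_timeseries`.

    Rows may be a single value or ``time,value`` pairs (the time column is
    ignored; the clock comes from the header).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise TimeSeriesFormatError("file too short: need 2 header lines and >= 1 row")
    rate = _parse_header_line(lines[0], "sample_rate_hz", 1)
    t0 = _parse_header_line(lines[1], "t0_s", 2)
    if rate <= 0:
        raise TimeSeriesFormatError("line 1: sample_rate_hz must be positive")
    values = []
    ncols = None
    for lineno, line in enumerate(lines[2:], start=3):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split(",")
        if ncols is None:
            ncols = len(fields)
            if ncols not in (1, 2):
                raise TimeSeriesFormatError(
                    f"line {lineno}: expected 1 or 2 columns, got {ncols}"
                )
        elif len(fields) != ncols:
            raise TimeSeriesFormatError(
                f"line {lineno}: inconsistent column count ({len(fields)} vs {ncols})"
            )
        try:
            values.append(float(fields[-1]))
        except ValueError as exc:
            raise TimeSeriesFormatError(f"line {lineno}: non-numeric row") from exc
    if not values:
        raise TimeSeriesFormatError("no data rows found")
    return TimeSeries(np.array(values), rate, t0)
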