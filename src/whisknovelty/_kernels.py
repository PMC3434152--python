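"""Jitted cores for the two inherently sequential recursions.

Both loops carry state from sample to sample (plant feedback; online weight
adaptation) and cannot be vectorized, so they are compiled with numba.
Floating-point semantics are strict (no fastmath), so results match an
equivalent pure-Python recursion bit for bit.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def bilinear_recursion(u, a1, a2, b1, b2, k, guard):
    """Second-order difference equation with optional bilinear input-state term.

    r[t] = -a1*r[t-1] - a2*r[t-2] + b1*u[t-1] + b2*u[t-2] + k*u[t-1]*r[t-1]

    Returns (r, diverged_index); diverged_index is -1 if |r| never exceeded
    ``guard``, else the first offending sample (r is valid up to there).
    """
    n = u.shape[0]
    r = np.zeros(n)
    for t in range(n):
        acc = 0.0
        if t >= 1:
            acc += -a1 * r[t - 1] + b1 * u[t - 1] + k * u[t - 1] * r[t - 1]
        if t >= 2:
            acc += -a2 * r[t - 2] + b2 * u[t - 2]
        r[t] = acc
        if np.abs(acc) > guard or not np.isfinite(acc):
            return r, t
    return r, -1


@numba.njit(cache=True)
def lms_run(
    u_pad,
    z_pad,
    target,
    w,
    n_taps,
    stride,
    use_motor,
    use_sensory,
    off_m,
    off_s,
    beta,
    snap_every,
    snaps,
):
    """Per-sample tap-delay LMS loop.

    ``u_pad``/``z_pad`` are the filter input signals left-padded with zeros so
    that ``pad + t - delay - j*stride`` is always a valid index; ``off_m`` and
    ``off_s`` equal ``pad - delay`` for the motor and sensory lines.  ``w`` is
    updated in place (motor taps first, then sensory).  Snapshots of the weight
    vector are stored every ``snap_every`` samples.

    Returns (e, y_hat, diverged_index), diverged_index -1 on success.
    """
    n = target.shape[0]
    e = np.empty(n)
    y_hat = np.empty(n)
    n_snap = snaps.shape[0]
    i_snap = 0
    w0_s = n_taps if use_motor else 0
    for t in range(n):
        acc = 0.0
        if use_motor:
            base = off_m + t
            for j in range(n_taps):
                acc += w[j] * u_pad[base - j * stride]
        if use_sensory:
            base = off_s + t
            for j in range(n_taps):
                acc += w[w0_s + j] * z_pad[base - j * stride]
        y_hat[t] = acc
        et = target[t] - acc
        e[t] = et
        if not np.isfinite(et):
            return e, y_hat, t
        if beta != 0.0:
            g = beta * et
            if use_motor:
                base = off_m + t
                for j in range(n_taps):
                    w[j] += g * u_pad[base - j * stride]
            if use_sensory:
                base = off_s + t
                for j in range(n_taps):
                    w[w0_s + j] += g * z_pad[base - j * stride]
        if snap_every > 0 and (t + 1) % snap_every == 0 and i_snap < n_snap:
            for i in range(w.shape[0]):
                snaps[i_snap, i] = w[i]
            i_snap += 1
    return e, y_hat, -1
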