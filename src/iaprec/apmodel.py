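"""Modified Aliev–Panfilov single-cell model.

The two-variable phenomenological model describes the cardiac action
potential with a normalized membrane potential ``v`` and a recovery
variable ``w``::

    dv/dt = k v (1 - v)(v - a) - v w
    dw/dt = eps(v, a, x) (k v - w)

``a`` is the excitation threshold, ``k`` scales the transmembrane
current, and the weighting function ``eps`` smoothly switches between
``x`` (below threshold) and ``1 - x`` (above threshold) through a steep
logistic of sharpness ``n``.  Eliminating ``w`` yields a single
second-order constraint ``F_AP(v, dv/dt, d2v/dt2, a, k, x) = 0`` that
vanishes on model solutions and serves as the pseudo-physics residual
in the reconstruction loss.

Time and voltage are dimensionless (t.u. / normalized units); mapping
onto seconds and millivolts happens in the synthetic-data layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "APParams",
    "Trajectory",
    "epsilon_smooth",
    "simulate_ap",
    "finite_diff",
    "physics_residual",
]


class InstabilityError(RuntimeError):
    """Raised when the fixed-step integration diverges."""


@dataclass(frozen=True)
class APParams:
    """Parameters of the modified Aliev–Panfilov model.

    a : excitation threshold, 0 < a < 1
    k : transmembrane current magnitude, > 0
    x : excitation/recovery balance, in [0, 1]
    n : sharpness of the smoothed step function (default 1000)
    eps_num : additive numerical guard applied where v or dv/dt vanish
    """

    a: float = 0.15
    k: float = 8.0
    x: float = 0.5
    n: float = 1000.0
    eps_num: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"excitation threshold a must be in (0, 1), got {self.a}")
        if self.k <= 0.0:
            raise ValueError(f"current magnitude k must be > 0, got {self.k}")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"balance x must be in [0, 1], got {self.x}")
        if self.n <= 0.0:
            raise ValueError(f"sharpness n must be > 0, got {self.n}")


@dataclass
class Trajectory:
    """A simulated (t, v, w) path on a uniform time grid (t.u.)."""

    t: np.ndarray
    v: np.ndarray
    w: np.ndarray
    dt: float

    def __len__(self) -> int:
        return self.t.size


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    # logistic with clipped argument; n*(v-a) easily overflows exp otherwise
    z = np.clip(z, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-z))


def epsilon_smooth(v: np.ndarray | float, params: APParams) -> np.ndarray | float:
    """Sigmoid-smoothed step weight eps(v, a, x).

    eps = x * sigma(n (a - v)) + (1 - x) * sigma(n (v - a)).  Values lie
    in [min(x, 1-x), max(x, 1-x)] and eps(a) = 0.5 for any x.
    """
    z = params.n * (np.asarray(v, dtype=float) - params.a)
    out = params.x * _sigmoid(-z) + (1.0 - params.x) * _sigmoid(z)
    if np.isscalar(v):
        return float(out)
    return out


def _eps_scalar(v: float, p: APParams) -> float:
    # scalar fast path for the integrator loop (math.exp beats numpy here)
    z = p.n * (v - p.a)
    if z > 500.0:
        z = 500.0
    elif z < -500.0:
        z = -500.0
    s = 1.0 / (1.0 + math.exp(-z))
    return p.x * (1.0 - s) + (1.0 - p.x) * s


def _derivs(v: float, w: float, p: APParams):
    dv = p.k * v * (1.0 - v) * (v - p.a) - v * w
    dw = _eps_scalar(v, p) * (p.k * v - w)
    return dv, dw


def simulate_ap(
    params: APParams,
    v0: float = 0.3,
    w0: float = 0.0,
    dt: float = 1e-3,
    T: float = 30.0,
) -> Trajectory:
    """Integrate the two-variable model with fixed-step classical RK4.

    A supra-threshold initial condition (``v0 > a``, ``w0 = 0``) elicits
    an upstroke toward ~1 followed by recovery toward 0; the model has
    no stimulus term.  (0, 0) is a fixed point.

    Raises
    ------
    InstabilityError
        if the state becomes non-finite (dt too large).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(T / dt))
    if n_steps < 10:
        raise ValueError("T/dt must be at least 10")
    t = np.arange(n_steps + 1) * dt
    v = np.empty(n_steps + 1)
    w = np.empty(n_steps + 1)
    v[0], w[0] = v0, w0
    vi, wi = float(v0), float(w0)
    for i in range(n_steps):
        k1v, k1w = _derivs(vi, wi, params)
        k2v, k2w = _derivs(vi + 0.5 * dt * k1v, wi + 0.5 * dt * k1w, params)
        k3v, k3w = _derivs(vi + 0.5 * dt * k2v, wi + 0.5 * dt * k2w, params)
        k4v, k4w = _derivs(vi + dt * k3v, wi + dt * k3w, params)
        vi = vi + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        wi = wi + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
        if not (np.isfinite(vi) and np.isfinite(wi)):
            raise InstabilityError(
                f"non-finite state at t={t[i + 1]:.4g} t.u.; reduce dt (dt={dt:g})"
            )
        v[i + 1], w[i + 1] = vi, wi
    return Trajectory(t=t, v=v, w=w, dt=dt)


def finite_diff(v: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference first and second derivatives on a uniform grid.

    Interior points use (v[i+1] - v[i-1]) / (2 dt) and
    (v[i+1] + v[i-1] - 2 v[i]) / dt^2; endpoints use one-sided
    second-order stencils so both outputs have the input length.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-D series of length >= 3")
    d1 = np.empty_like(v)
    d2 = np.empty_like(v)
    d1[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt)
    d2[1:-1] = (v[2:] + v[:-2] - 2.0 * v[1:-1]) / dt**2
    d1[0] = (-3.0 * v[0] + 4.0 * v[1] - v[2]) / (2.0 * dt)
    d1[-1] = (3.0 * v[-1] - 4.0 * v[-2] + v[-3]) / (2.0 * dt)
    d2[0] = (2.0 * v[0] - 5.0 * v[1] + 4.0 * v[2] - v[3]) / dt**2 if v.size >= 4 else d2[1]
    d2[-1] = (
        (2.0 * v[-1] - 5.0 * v[-2] + 4.0 * v[-3] - v[-4]) / dt**2 if v.size >= 4 else d2[-2]
    )
    return d1, d2


def guard_small(arr: np.ndarray, eps: float) -> np.ndarray:
    """Add +eps at entries that are numerically zero (the eps_num guard).

    The guard is applied only at vanishing samples, not in a band around
    zero, so it never perturbs the residual away from those samples.
    """
    out = np.asarray(arr, dtype=float).copy()
    mask = np.abs(out) < 1e-12
    out[mask] += eps
    return out


def physics_residual(v: np.ndarray, params: APParams, dt: float) -> np.ndarray:
    """Pseudo-physics residual F_AP evaluated along a sampled waveform.

    F_AP = v^-2 (v')^2 - v^-1 v'' - v' [eps(v)/v - k(1 - 2v + a)]
           - k eps(v) (v^2 - a v + a)

    with derivatives from :func:`finite_diff` and the eps_num guard
    added where v or v' vanish.  On solutions of the model the residual
    is zero up to discretisation error, so max|F_AP| -> 0 as dt -> 0.
    """
    v = np.asarray(v, dtype=float)
    d1, d2 = finite_diff(v, dt)
    vg = guard_small(v, params.eps_num)
    d1g = guard_small(d1, params.eps_num)
    eps_v = epsilon_smooth(v, params)
    return (
        vg**-2 * d1g**2
        - vg**-1 * d2
        - d1g * (eps_v / vg - params.k * (1.0 - 2.0 * v + params.a))
        - params.k * eps_v * (v**2 - params.a * v + params.a)
    )
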