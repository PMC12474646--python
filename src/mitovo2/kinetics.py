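"""Stop-flow oxygen kinetics.

Under stop-flow, mitoPO2 declines through Michaelis-Menten tissue consumption
while diffusive influx from surrounding tissue partially refills the
compressed volume:

    dP/dt = -V0 * P / (P50 + P) + Z * (P0 - P)

with V0 the initial decline slope after compression (mmHg/s), P50 the PO2 at
half-maximal consumption (mmHg), P0 the mean PO2 before compression (mmHg)
and Z the diffusive influx coefficient (1/s).  The maximal oxygen consumption
V_max of a measurement is the steepest tangent of the model curve.

The ODE is integrated with classic 4th-order Runge-Kutta.  Because the local
relaxation rate lambda(P) = V0*P50/(P50+P)^2 + Z can exceed the RK4 stability
bound at the 1-Hz output grid when P approaches 0 with small P50, each output
step is internally subdivided with h = 0.05 / lambda(P); the output is sampled
on the requested grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["KineticParams", "dpdt", "simulate_decay", "vmax_of_curve",
           "equilibrium_po2"]


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the stop-flow decay model (all per measurement)."""

    v0: float   # mmHg/s, initial slope after compression
    p50: float  # mmHg, PO2 at half V_max
    p0: float   # mmHg, mean PO2 before compression
    z: float    # 1/s, diffusive influx coefficient

    def __post_init__(self) -> None:
        if not (self.v0 >= 0 and self.p50 > 0 and self.p0 >= 0 and self.z >= 0):
            raise ValueError(
                f"invalid kinetic parameters: require v0>=0, p50>0, p0>=0, z>=0, "
                f"got v0={self.v0}, p50={self.p50}, p0={self.p0}, z={self.z}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.v0, self.p50, self.p0, self.z], dtype=float)


def dpdt(p: float, params: KineticParams) -> float:
    """Instantaneous rate of mitoPO2 change at oxygen tension ``p`` (mmHg)."""
    if p < 0:
        raise ValueError(f"mitoPO2 must be non-negative, got {p}")
    return -(params.v0 * p) / (params.p50 + p) + params.z * (params.p0 - p)


@njit(cache=False)
def _rk4_path(v0, p50, p0, z, p_init, n_out, dt):  # pragma: no cover - jitted
    out = np.empty(n_out + 1)
    p = p_init
    clipped = False
    out[0] = p
    for i in range(n_out):
        t_rem = dt
        while t_rem > 0.0:
            x = p
            k1 = -v0 * x / (p50 + x) + z * (p0 - x)
            # substep limited by the local relaxation rate (stability) and
            # by the per-step state change (truncation at the decay knee)
            lam = v0 * p50 / (p50 + p) ** 2 + z
            h = 0.05 / lam if lam > 0.0 else t_rem
            df = abs(k1)
            if df > 0.0 and 0.2 / df < h:
                h = 0.2 / df
            if h > t_rem:
                h = t_rem
            if h < 1e-6:
                h = 1e-6
            x = p + 0.5 * h * k1
            if x < 0.0:
                x = 0.0
            k2 = -v0 * x / (p50 + x) + z * (p0 - x)
            x = p + 0.5 * h * k2
            if x < 0.0:
                x = 0.0
            k3 = -v0 * x / (p50 + x) + z * (p0 - x)
            x = p + h * k3
            if x < 0.0:
                x = 0.0
            k4 = -v0 * x / (p50 + x) + z * (p0 - x)
            p = p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if p < 0.0:
                p = 0.0
                clipped = True
            if not np.isfinite(p):
                return out, i, clipped
            t_rem -= h
        out[i + 1] = p
    return out, -1, clipped


def simulate_decay(params: KineticParams, duration: float, dt: float = 1.0,
                   p_init: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the stop-flow decay and return ``(t, p)`` on the output grid.

    Parameters
    ----------
    params : KineticParams
    duration : float
        Total simulated time in seconds (> 0).
    dt : float
        Output grid step, 0 < dt <= 1 s.  The integrator substeps internally,
        so ``dt`` only sets the sampling of the returned trajectory.
    p_init : float, optional
        Starting oxygen tension; defaults to ``params.p0`` (the fit treats the
        pre-compression mean as the curve's starting level).

    Returns
    -------
    t, p : ndarray
        ``t = 0, dt, ..., n*dt`` with ``n = round(duration/dt)`` and the
        corresponding mitoPO2 values (clipped at 0 on numerical undershoot,
        with a warning).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not (0 < dt <= 1):
        raise ValueError("dt must satisfy 0 < dt <= 1 s")
    if p_init is None:
        p_init = params.p0
    if p_init < 0:
        raise ValueError("p_init must be non-negative")
    n_out = int(round(duration / dt))
    p, bad_step, clipped = _rk4_path(params.v0, params.p50, params.p0,
                                     params.z, float(p_init), n_out, float(dt))
    if bad_step >= 0:
        raise FloatingPointError(
            f"RK4 integration diverged (non-finite state) at output step {bad_step}"
        )
    if clipped:
        warnings.warn("trajectory undershot 0 mmHg and was clipped",
                      RuntimeWarning, stacklevel=2)
    t = np.arange(n_out + 1) * dt
    return t, p


def vmax_of_curve(series: np.ndarray, dt: float = 1.0) -> float:
    """Steepest drop of a model curve, as a positive rate in mmHg/s.

    ``series`` is the sampled curve; the tangent is taken at the segment with
    the most negative per-step slope.  A curve with no declining segment
    yields 0 with a warning.
    """
    p = np.asarray(series, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 samples to take a slope")
    slopes = np.diff(p) / dt
    steepest = slopes.min()
    if steepest >= 0:
        if steepest > 0:
            warnings.warn("series never declines; V_max set to 0",
                          RuntimeWarning, stacklevel=2)
        return 0.0
    return float(-steepest)


def equilibrium_po2(params: KineticParams) -> float:
    """Stable equilibrium P* of the decay ODE (consumption = influx).

    Solves v0*p/(p50+p) = z*(p0-p); the positive root of a quadratic in p.
    For z = 0 the equilibrium is 0.
    """
    v0, p50, p0, z = params.v0, params.p50, params.p0, params.z
    if z == 0:
        return 0.0
    # z*p^2 + (v0 + z*p50 - z*p0)*p - z*p50*p0 = 0
    a, b, c = z, v0 + z * p50 - z * p0, -z * p50 * p0
    disc = b * b - 4 * a * c
    return float((-b + np.sqrt(disc)) / (2 * a))
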