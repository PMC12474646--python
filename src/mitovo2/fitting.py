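"""Per-measurement kinetic fits and subject-level mitoVO2.

Each cleaned measurement segment is fit by bounded nonlinear least squares:
the decay ODE is integrated (RK4) from the candidate P0 and compared with
the observed 1-Hz samples; the free parameters are (V0, P50, P0, Z).  V_max
is then the steepest tangent of the fitted model curve, evaluated on a fine
grid, and a subject's mitoVO2 is the mean V_max over that subject's
converged fits.

P50 and Z trade off on short segments, so individual parameters can be
weakly identified; the fitted trajectory and its V_max are the quantities
the pipeline relies on.  Non-convergence is reported (``converged=False``,
V_max omitted) rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .io import MeasurementSegment, Trace
from .kinetics import KineticParams, simulate_decay, vmax_of_curve

__all__ = ["FitResult", "MichaelisMentenDecay", "initial_guess",
           "fit_segment", "subject_mitovo2", "BOUNDS"]

#: (lower, upper) box for (v0, p50, p0, z)
BOUNDS = (np.array([0.0, 0.1, 0.0, 0.0]), np.array([100.0, 50.0, 150.0, 1.0]))
_VMAX_DT = 0.01   # fine grid for the steepest-tangent readout
_P50_STARTS = (0.5, 5.0, 15.0)  # multi-start grid; p50/z trade off locally


@dataclass
class FitResult:
    params: KineticParams | None
    vmax: float | None  # mmHg/s; None when the fit did not converge
    rmse: float | None  # mmHg
    converged: bool
    n_points: int


def initial_guess(segment: MeasurementSegment | np.ndarray,
                  trace: Trace | None = None,
                  start_index: int | None = None) -> KineticParams:
    """Data-driven starting point for the nonlinear fit.

    V0 from the mean of the first three finite differences of the segment;
    P0 from the mean of up to 10 pre-compression samples (at least 3, else
    the start value); P50 and Z from fixed physiological priors (5 mmHg,
    0.01 1/s).
    """
    values = segment.mitopo2 if isinstance(segment, MeasurementSegment) \
        else np.asarray(segment, dtype=float)
    if values.size < 4:
        raise ValueError("segment too short to estimate the initial slope "
                         "(need >= 4 samples)")
    v0 = float(max(-np.mean(np.diff(values[:4])), 0.0))
    if start_index is None and isinstance(segment, MeasurementSegment):
        start_index = segment.start_index
    if trace is not None and start_index is not None and start_index >= 3:
        lo = max(start_index - 10, 0)
        p0 = float(np.mean(trace.mitopo2[lo: start_index]))
    else:
        p0 = float(values[0])
    return KineticParams(v0=v0, p50=5.0, p0=max(p0, 0.0), z=0.01)


class MichaelisMentenDecay(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of the stop-flow decay model to one
    measurement segment.

    Parameters
    ----------
    max_restarts : int
        Jittered restarts attempted when the optimizer does not converge.
    tol : float
        Cost and step tolerances handed to the trust-region solver.

    Attributes (after ``fit``)
    --------------------------
    params_ : KineticParams, vmax_ : float, rmse_ : float,
    converged_ : bool, n_points_ : int
    """

    def __init__(self, max_restarts: int = 3, tol: float = 1e-10,
                 max_nfev: int = 200):
        self.max_restarts = max_restarts
        self.tol = tol
        self.max_nfev = max_nfev

    def _residuals(self, x: np.ndarray, observed: np.ndarray) -> np.ndarray:
        params = KineticParams(*np.maximum(x, [0.0, 1e-6, 0.0, 0.0]))
        n = observed.size
        _, model = simulate_decay(params, duration=n - 1, dt=1.0,
                                  p_init=params.p0)
        return model - observed

    def fit(self, X: MeasurementSegment | np.ndarray, y=None,
            initial: KineticParams | None = None) -> "MichaelisMentenDecay":
        observed = X.mitopo2 if isinstance(X, MeasurementSegment) \
            else np.asarray(X, dtype=float)
        if observed.size < 11:
            raise ValueError("segment must have >= 11 samples "
                             "(shorter ones are filtered upstream)")
        if initial is None:
            initial = initial_guess(observed)
        lo, hi = BOUNDS
        rng = np.random.default_rng(0)  # deterministic restart jitter
        best = None
        import warnings as _w

        def attempt(x0: np.ndarray):
            nonlocal best
            try:
                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    res = least_squares(
                        self._residuals, x0, args=(observed,), bounds=(lo, hi),
                        method="trf", ftol=self.tol, xtol=self.tol,
                        x_scale="jac", max_nfev=self.max_nfev)
            except (FloatingPointError, ValueError):
                return
            if best is None or res.cost < best.cost:
                best = res

        # systematic multi-start over p50 (locally traded off against z),
        # then jittered restarts if nothing converged
        p_eq = float(observed[-3:].mean())  # apparent equilibrium level
        for p50_start in _P50_STARTS:
            x0 = initial.as_array()
            x0[1] = p50_start
            attempt(np.clip(x0, lo, hi))
            if 0 < p_eq < 0.8 * x0[2]:
                # consumption balances influx at the observed plateau:
                # z ~= v0*p_eq / ((p50+p_eq)*(p0-p_eq))
                x0_eq = x0.copy()
                x0_eq[3] = x0[0] * p_eq / ((p50_start + p_eq)
                                           * (x0[2] - p_eq))
                attempt(np.clip(x0_eq, lo, hi))
            if best is not None and best.success and best.cost < 1e-12:
                break
        restarts = 0
        while (best is None or not best.success) and restarts < self.max_restarts:
            x0 = np.clip(initial.as_array() * rng.lognormal(0.0, 0.3, 4), lo, hi)
            attempt(x0)
            restarts += 1
        self.n_points_ = int(observed.size)
        if best is None:
            self.converged_ = False
            self.params_ = None
            self.vmax_ = None
            self.rmse_ = None
            return self
        x = np.maximum(best.x, [0.0, 1e-6, 0.0, 0.0])
        self.params_ = KineticParams(*x)
        self.rmse_ = float(np.sqrt(np.mean(best.fun ** 2)))
        self.converged_ = bool(best.success)
        if self.converged_:
            import warnings as _warn
            with _warn.catch_warnings():
                _warn.simplefilter("ignore", RuntimeWarning)
                _, fine = simulate_decay(self.params_,
                                         duration=observed.size - 1,
                                         dt=_VMAX_DT, p_init=self.params_.p0)
                self.vmax_ = vmax_of_curve(fine, dt=_VMAX_DT)
        else:
            self.vmax_ = None
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Model mitoPO2 at integer-second times ``t`` (from the fitted
        trajectory's start)."""
        if self.params_ is None:
            raise RuntimeError("fit did not produce parameters")
        t = np.asarray(t)
        _, p = simulate_decay(self.params_, duration=float(t.max() or 1),
                              dt=1.0, p_init=self.params_.p0)
        return p[t.astype(int)]


def fit_segment(segment: MeasurementSegment | np.ndarray,
                guess: KineticParams | None = None) -> FitResult:
    """Fit one segment and package the result."""
    est = MichaelisMentenDecay().fit(segment, initial=guess)
    return FitResult(params=est.params_, vmax=est.vmax_, rmse=est.rmse_,
                     converged=est.converged_, n_points=est.n_points_)


def subject_mitovo2(fit_results: list[FitResult]) -> float | None:
    """Arithmetic mean V_max over converged fits; None when a subject has no
    valid measurement."""
    vmaxes = [r.vmax for r in fit_results if r.converged and r.vmax is not None]
    if not vmaxes:
        return None
    return float(np.mean(vmaxes))
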