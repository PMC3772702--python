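"""Numerical integration, steady-state finding and transient features.

Time courses are computed with adaptive error control (relative
tolerance 1e-8, absolute 1e-10) on a uniform output grid.  The only
unbounded regime of the model is deletion of the Ime2→Ime1 negative
feedback, in which Ime2 grows without bound; any component exceeding
the blow-up bound (1e3; wild-type levels are O(1)) flags the trajectory
as diverged and truncates it.

Steady states are obtained by integrating far past the transient
(t = 500 h) and polishing the endpoint with a damped Newton iteration
on the analytic Jacobian; clamped (knocked-out) variables are held at
zero and excluded from the Newton system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model_core import VARIABLES, ParameterSet, jacobian, mitotic_initial_state, rhs

__all__ = [
    "BLOWUP_BOUND",
    "Trajectory",
    "TransientFeatures",
    "integrate",
    "find_steady_state",
    "transient_features",
]

#: Any state component above this value declares divergence.
BLOWUP_BOUND = 1e3

_RTOL = 1e-8
_ATOL = 1e-10

# Local maxima with prominence below this fraction of the signal range
# (floored at 1e-6 absolute) are near-equilibrium ripple, not
# oscillation structure.
_PEAK_PROMINENCE_REL = 1e-3


@dataclass(frozen=True)
class Trajectory:
    """A dense solution on a uniform time grid (hours)."""

    t: np.ndarray            # shape (m,), strictly increasing, starts at 0
    y: np.ndarray            # shape (m, 6), one state per grid point
    diverged: bool

    def __post_init__(self) -> None:
        if len(self.t) != len(self.y):
            raise ValueError("time grid and state matrix lengths disagree")

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]

    def series(self, variable: str) -> np.ndarray:
        return self.y[:, VARIABLES.index(variable)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(VARIABLES))
        df.insert(0, "time_h", self.t)
        return df


@dataclass(frozen=True)
class TransientFeatures:
    """Summary of a single-variable transient profile.

    Peak fields are ``None`` for profiles without a proper interior
    maximum (monotone or clamped-at-zero trajectories).
    """

    peak_time: float | None
    peak_value: float | None
    width_at_half_max: float | None
    n_local_maxima: int
    damped_oscillation: bool
    steady_value: float


def _solver_rhs(params: ParameterSet, variant):
    eff, clamped = (params, ()) if variant is None else variant.resolve(params)
    clamped = list(clamped)

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        if clamped:
            yc = yc.copy()
            yc[clamped] = 0.0
        return rhs(yc, eff)

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        return jacobian(yc, eff, variant)

    return fun, jac, eff, clamped


def integrate(
    variant,
    params: ParameterSet | None = None,
    init: Sequence[float] | None = None,
    t_end: float = 24.0,
    n_points: int = 961,
    method: str = "LSODA",
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trajectory:
    """Integrate the model on a uniform grid of ``n_points`` over [0, t_end].

    Returns a :class:`Trajectory`; ``diverged`` is set (and the grid
    truncated) if any component crosses :data:`BLOWUP_BOUND`.  The
    default grid (24 h, 0.025-h spacing) resolves the ~6-h Ime1 peak.
    """
    if params is None:
        params = ParameterSet()
    if init is None:
        init = mitotic_initial_state()
    y0 = np.asarray(init, dtype=float)
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    fun, jac, _, clamped = _solver_rhs(params, variant)
    if clamped:
        y0 = y0.copy()
        y0[clamped] = 0.0

    def blowup(t, y):
        return BLOWUP_BOUND - np.max(y)

    blowup.terminal = True
    blowup.direction = -1

    grid = np.linspace(0.0, t_end, n_points)
    kwargs = dict(rtol=rtol, atol=atol, t_eval=grid, events=blowup, dense_output=False)
    if method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = jac
    sol = solve_ivp(fun, (0.0, t_end), y0, method=method, **kwargs)

    diverged = bool(sol.t_events[0].size)
    if not sol.success and not diverged:
        raise RuntimeError(f"integration failed: {sol.message}")

    t = sol.t
    y = np.maximum(sol.y.T, 0.0)
    if clamped:
        y[:, clamped] = 0.0
    if t.size == 0 or t[0] != 0.0:  # event before first output point
        t = np.concatenate([[0.0], t])
        y = np.vstack([y0, y])
    return Trajectory(t=t, y=y, diverged=diverged)


def _newton_polish(
    x0: np.ndarray,
    params: ParameterSet,
    variant,
    free: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-13,
) -> tuple[np.ndarray, bool]:
    """Damped Newton on the free components of rhs; returns (state, ok).

    ``ok`` is False if the iteration leaves the admissible box or fails
    to reduce the residual.
    """
    x = x0.copy()
    for _ in range(max_iter):
        f = rhs(x, params, variant)[free]
        norm = np.max(np.abs(f))
        if norm < tol:
            return x, True
        J = jacobian(x, params, variant)[np.ix_(free, free)]
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return x, False
        lam = 1.0
        for _ in range(30):
            trial = x.copy()
            trial[free] = x[free] + lam * step
            if np.all(trial > -1e-9) and np.all(trial[:3] < 1.0 + 1e-9):
                trial = np.clip(trial, 0.0, None)
                fnew = rhs(trial, params, variant)[free]
                if np.max(np.abs(fnew)) < norm:
                    x = trial
                    break
            lam *= 0.5
        else:
            return x, norm < 1e-10
    return x, np.max(np.abs(rhs(x, params, variant)[free])) < 1e-10


def find_steady_state(
    variant,
    params: ParameterSet | None = None,
    init: Sequence[float] | None = None,
    t_relax: float = 500.0,
) -> tuple[np.ndarray, bool]:
    """Long-time state of the model, Newton-polished to a fixed point.

    Returns ``(state, converged)``.  ``converged`` requires the
    max-norm of the right-hand side at the result to be below 1e-10 and
    all state invariants to hold; divergence yields ``converged=False``
    with the truncated endpoint.
    """
    if params is None:
        params = ParameterSet()
    traj = integrate(variant, params, init, t_end=t_relax, n_points=501)
    end = traj.final_state
    if traj.diverged:
        return end, False
    _, clamped = (params, ()) if variant is None else variant.resolve(params)
    free = np.array([i for i in range(6) if i not in clamped], dtype=int)
    if free.size == 0:
        return end, True
    polished, ok = _newton_polish(end, params, variant, free)
    if not ok:
        polished = end  # fall back to the relaxed integrator endpoint
    resid = np.max(np.abs(rhs(polished, params, variant)))
    admissible = (
        np.all(polished >= 0.0)
        and np.all(polished[:3] <= 1.0 + 1e-9)
        and np.all(np.isfinite(polished))
    )
    return polished, bool(resid < 1e-10 and admissible)


def transient_features(traj: Trajectory, variable: str) -> TransientFeatures:
    """Peak location/height/width and oscillation diagnostics for one variable.

    The global interior maximum is refined by local quadratic
    interpolation; the width is the full width at half maximum measured
    above a zero baseline (the pre-stimulus level of the meiotic
    proteins).  ``damped_oscillation`` requires at least two local
    maxima of strictly decreasing height.
    """
    v = traj.series(variable)
    t = traj.t
    prominence = max(1e-6, _PEAK_PROMINENCE_REL * (np.max(v) - np.min(v)))
    peaks, _ = find_peaks(v, prominence=prominence)
    n_max = int(len(peaks))
    damped = bool(n_max >= 2 and np.all(np.diff(v[peaks]) < 0))
    steady = float(v[-1])
    if traj.diverged or n_max == 0:
        return TransientFeatures(None, None, None, n_max, damped, steady)

    k = peaks[int(np.argmax(v[peaks]))]
    # quadratic refinement through the three points around the grid maximum
    tk, vk = t[k - 1 : k + 2], v[k - 1 : k + 2]
    denom = (vk[0] - 2 * vk[1] + vk[2])
    if denom < 0:
        dt = t[1] - t[0]
        shift = 0.5 * (vk[0] - vk[2]) / denom
        peak_time = float(t[k] + shift * dt)
        peak_value = float(vk[1] - 0.25 * (vk[0] - vk[2]) * shift)
    else:
        peak_time = float(t[k])
        peak_value = float(v[k])

    half = 0.5 * peak_value
    width = None
    left = right = None
    for i in range(k, 0, -1):
        if v[i - 1] < half <= v[i]:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    for i in range(k, len(v) - 1):
        if v[i] >= half > v[i + 1]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    if left is not None and right is not None:
        width = float(right - left)
    return TransientFeatures(peak_time, peak_value, width, n_max, damped, steady)
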