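"""Equilibrium continuation, stability classification and bistability.

Equilibria are located by multi-start Newton/Powell root finding on the
right-hand side.  The start grid seeds the three conserved-pool
fractions at their quasi-steady closed forms, Ime1 on a short list of
plausible levels, and Ime2 on log-spaced points reaching well above 1
(the high-efficiency branch can sit far above the wild-type level).
Stability is read off the eigenvalues of the analytic Jacobian
restricted to the free (non-clamped) variables.

One-parameter branches are assembled by sweeping a grid in both
directions with warm starts from neighbouring grid points plus fresh
multi-starts at every step, so disconnected branches are found without
pseudo-arclength bookkeeping — the 6-D system is cheap enough that
robustness beats tangent tracking.  Fold (saddle-node) points bounding
a bistable interval are refined by bisection on the count of stable
equilibria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
from scipy.optimize import root

from .model_core import PARAM_NAMES, ParameterSet, jacobian, rhs
from .perturbation import ModelVariant, override, wild_type

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "BistableInterval",
    "equilibria_at",
    "scan_1d",
    "scan_coupled_pka",
    "bistable_interval",
]

_RESIDUAL_TOL = 1e-10
_DEDUP_TOL = 1e-6
_STAB_MARGIN = 1e-8

#: Coupled-parameter pseudo-name: one factor scaling both PKA-mediated
#: phosphorylation rates (p_sok2 and p_rim11).
PKA_SCALE = "pka_scale"


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the model with its linear stability."""

    state: np.ndarray
    stability: str                   # "stable" | "unstable"
    leading_real_eigenvalue: float   # per hour

    @property
    def ime2(self) -> float:
        return float(self.state[5])


@dataclass(frozen=True)
class EquilibriumBranch:
    """Equilibria along a scanned parameter."""

    parameter: str
    values: np.ndarray                       # strictly monotone grid
    equilibria: list[list[Equilibrium]]      # one list per grid value

    def stable_counts(self) -> np.ndarray:
        return np.array(
            [sum(e.stability == "stable" for e in eqs) for eqs in self.equilibria]
        )


@dataclass(frozen=True)
class BistableInterval:
    """Parameter interval on which two stable equilibria coexist."""

    parameter: str
    lower: float
    upper: float
    hill_n: int


def _apply_param(variant: ModelVariant, name: str, value: float) -> ModelVariant:
    if name == PKA_SCALE:
        base = ParameterSet()
        v = override(variant, "p_sok2", base.p_sok2 * value)
        return override(v, "p_rim11", base.p_rim11 * value)
    if name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {name!r}")
    return override(variant, name, value)


def _start_points(params: ParameterSet, variant: ModelVariant) -> np.ndarray:
    """Multi-start grid: quasi-steady pools × Ime1 levels × log-spaced Ime2."""
    p, _ = variant.resolve(params)
    R = p.u_rim11 / (p.u_rim11 + p.p_rim11) if (p.u_rim11 + p.p_rim11) > 0 else 0.0
    U = (
        p.p_ume6 * R / (p.p_ume6 * R + p.u_ume6)
        if (p.p_ume6 * R + p.u_ume6) > 0
        else 0.0
    )
    ime1_grid = (0.01, 0.05, 0.2, 0.5, 1.0)
    ime2_grid = np.geomspace(1e-3, 50.0, 12)
    starts = []
    for I in ime1_grid:
        if np.isinf(p.c_sok2):
            g = 1.0
        else:
            g = p.c_sok2 / (p.c_sok2 + I)
        S = p.p_sok2 * g / (p.p_sok2 * g + p.u_sok2) if p.u_sok2 > 0 else 1.0
        P = p.p_ime1 * R * I / p.d_pime1 if p.d_pime1 > 0 else 0.0
        for M in ime2_grid:
            starts.append([R, U, S, I, P, M])
    return np.array(starts)


def _classify(
    x: np.ndarray, params: ParameterSet, variant: ModelVariant, free: np.ndarray
) -> Equilibrium:
    J = jacobian(x, params, variant)[np.ix_(free, free)]
    lead = float(np.max(np.linalg.eigvals(J).real))
    stability = "stable" if lead < -_STAB_MARGIN else "unstable"
    return Equilibrium(state=x.copy(), stability=stability, leading_real_eigenvalue=lead)


def _admissible(x: np.ndarray) -> bool:
    return bool(
        np.all(np.isfinite(x))
        and np.all(x >= -1e-8)
        and np.all(x[:3] <= 1.0 + 1e-8)
    )


def equilibria_at(
    variant: ModelVariant | None = None,
    params: ParameterSet | None = None,
    param_name: str | None = None,
    value: float | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> list[Equilibrium]:
    """All distinct equilibria of the (possibly perturbed) model.

    ``param_name``/``value`` optionally override one parameter (or the
    coupled ``"pka_scale"``) on top of ``variant``.  ``extra_starts``
    adds warm-start states to the multi-start grid.  Equilibria are
    deduplicated at max-norm 1e-6 and sorted by the Ime2 coordinate.
    """
    if params is None:
        params = ParameterSet()
    if variant is None:
        variant = wild_type()
    if param_name is not None:
        if value is None:
            raise ValueError("value required when param_name is given")
        if value < 0:
            raise ValueError("parameter value must be >= 0")
        variant = _apply_param(variant, param_name, value)
    _, clamped = variant.resolve(params)
    free = np.array([i for i in range(6) if i not in clamped], dtype=int)

    def fun(xf: np.ndarray) -> np.ndarray:
        x = np.zeros(6)
        x[free] = np.maximum(xf, 0.0)
        return rhs(x, params, variant)[free]

    def jac(xf: np.ndarray) -> np.ndarray:
        x = np.zeros(6)
        x[free] = np.maximum(xf, 0.0)
        return jacobian(x, params, variant)[np.ix_(free, free)]

    starts = list(_start_points(params, variant)) + [
        np.asarray(s, dtype=float) for s in extra_starts
    ]
    found: list[np.ndarray] = []
    for s in starts:
        sol = root(fun, s[free], jac=jac, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        x = np.zeros(6)
        x[free] = np.maximum(sol.x, 0.0)
        if np.max(np.abs(rhs(x, params, variant))) > _RESIDUAL_TOL:
            continue
        if not _admissible(x):
            continue
        x = np.clip(x, 0.0, None)
        if any(np.max(np.abs(x - f)) < _DEDUP_TOL for f in found):
            continue
        found.append(x)
    if not found:
        warnings.warn("no equilibrium found from any start point", stacklevel=2)
        return []
    eqs = [_classify(x, params, variant, free) for x in found]
    eqs.sort(key=lambda e: e.ime2)
    return eqs


def _grid(lo: float, hi: float, n: int, scale: str) -> np.ndarray:
    if scale == "log":
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


def _sweep(
    variant: ModelVariant,
    params: ParameterSet,
    param_name: str,
    values: np.ndarray,
) -> list[list[Equilibrium]]:
    """Bidirectional warm-started sweep; equilibria merged per grid value."""
    per_value: list[list[Equilibrium]] = [[] for _ in values]

    def merge(i: int, eqs: list[Equilibrium]) -> None:
        for e in eqs:
            if not any(
                np.max(np.abs(e.state - o.state)) < _DEDUP_TOL for o in per_value[i]
            ):
                per_value[i].append(e)

    for order in (range(len(values)), range(len(values) - 1, -1, -1)):
        warm: list[np.ndarray] = []
        for i in order:
            eqs = equilibria_at(
                variant, params, param_name, float(values[i]), extra_starts=warm
            )
            merge(i, eqs)
            warm = [e.state for e in per_value[i]]
    for eqs in per_value:
        eqs.sort(key=lambda e: e.ime2)
    return per_value


def scan_1d(
    variant: ModelVariant | None = None,
    params: ParameterSet | None = None,
    param_name: str = "c2",
    value_range: tuple[float, float] = (1e-3, 1.0),
    n_steps: int = 41,
    scale: str = "log",
) -> EquilibriumBranch:
    """One-parameter equilibrium branch over ``value_range``.

    Half-maximum constants are scanned on a log grid by default (they
    vary over orders of magnitude); pass ``scale="linear"`` for rates.
    """
    if params is None:
        params = ParameterSet()
    if variant is None:
        variant = wild_type()
    lo, hi = value_range
    if not (0 <= lo < hi):
        raise ValueError(f"invalid range {value_range}")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    values = _grid(lo, hi, n_steps, scale)
    per_value = _sweep(variant, params, param_name, values)
    return EquilibriumBranch(parameter=param_name, values=values, equilibria=per_value)


def scan_coupled_pka(
    variant: ModelVariant | None = None,
    params: ParameterSet | None = None,
    scale_range: tuple[float, float] = (0.05, 2.0),
    n_steps: int = 41,
) -> EquilibriumBranch:
    """Branch over a common scale factor on the PKA-mediated rates.

    The factor multiplies both ``p_sok2`` and ``p_rim11``; lowering it
    emulates reduced PKA activity under meiotic conditions.
    """
    if params is None:
        params = ParameterSet()
    if variant is None:
        variant = wild_type()
    lo, hi = scale_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid scale range {scale_range}")
    values = _grid(lo, hi, n_steps, "log")
    per_value = _sweep(variant, params, PKA_SCALE, values)
    return EquilibriumBranch(parameter=PKA_SCALE, values=values, equilibria=per_value)


def _stable_count(
    variant: ModelVariant, params: ParameterSet, param_name: str, value: float,
    warm: Sequence[np.ndarray] = (),
) -> int:
    eqs = equilibria_at(variant, params, param_name, value, extra_starts=warm)
    return sum(e.stability == "stable" for e in eqs)


def bistable_interval(
    variant: ModelVariant | None = None,
    params: ParameterSet | None = None,
    param_name: str = "c2",
    value_range: tuple[float, float] = (0.1, 2.0),
    hill_n: int | None = None,
    n_steps: int = 33,
    tol: float = 1e-3,
    scale: str = "log",
) -> BistableInterval | None:
    """Parameter interval with coexisting stable equilibria, or ``None``.

    The grid scan locates sign changes of the predicate "≥ 2 stable
    equilibria"; each bounding fold point is then refined by bisection
    to parameter tolerance ``tol``.
    """
    if params is None:
        params = ParameterSet()
    if variant is None:
        variant = wild_type()
    if hill_n is not None:
        params = params.with_overrides(hill_n=int(hill_n))
    branch = scan_1d(variant, params, param_name, value_range, n_steps, scale)
    multi = branch.stable_counts() >= 2
    if not np.any(multi):
        return None
    values = branch.values
    idx = np.nonzero(multi)[0]
    lo_in, hi_in = values[idx[0]], values[idx[-1]]

    warm = [e.state for eqs in branch.equilibria for e in eqs]

    def bisect(a: float, b: float, inside_is_upper: bool) -> float:
        # invariant: predicate(multi) holds at one end only
        while b - a > tol:
            mid = 0.5 * (a + b)
            if _stable_count(variant, params, param_name, mid, warm) >= 2:
                if inside_is_upper:
                    b = mid
                else:
                    a = mid
            else:
                if inside_is_upper:
                    a = mid
                else:
                    b = mid
        return 0.5 * (a + b)

    if idx[0] > 0:
        lower = bisect(float(values[idx[0] - 1]), float(lo_in), inside_is_upper=True)
    else:
        lower = float(lo_in)
    if idx[-1] < len(values) - 1:
        upper = bisect(float(hi_in), float(values[idx[-1] + 1]), inside_is_upper=False)
    else:
        upper = float(hi_in)
    return BistableInterval(
        parameter=param_name, lower=lower, upper=upper, hill_n=params.hill_n
    )
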