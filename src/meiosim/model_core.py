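"""Core ODE model of yeast meiotic initiation.

Six dimensionless state variables track the early meiotic signaling
cascade in *Saccharomyces cerevisiae*:

====== =========================================================
index  variable
====== =========================================================
0      Rim11   — unphosphorylated (active) fraction of the Rim11
                kinase pool
1      pUme6   — phosphorylated (active) fraction of the Ume6 pool
2      pSok2   — phosphorylated (repressive) fraction of the Sok2
                pool
3      Ime1    — unphosphorylated master regulator, relative level
4      pIme1   — Rim11-phosphorylated Ime1, relative level
5      Ime2    — early meiotic kinase, relative level (the pathway
                readout; may exceed 1 under perturbation)
====== =========================================================

Rim11, Ume6 and Sok2 are conserved one-unit pools, so their active
fractions live in [0, 1].  Ime1, pIme1 and Ime2 are synthesized and
degraded and are only bounded below by 0.  Time is measured in hours;
all rate parameters are per hour.

The network couples three feedback loops: a double-negative loop
between pSok2 and Ime1 (mutual inhibition, functionally a positive
loop), a negative loop in which Ime2 promotes Ime1 degradation, and
positive auto-regulation of Ime2 through a cooperative Hill term.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "VARIABLES",
    "PARAM_NAMES",
    "INF_CAPABLE",
    "ParameterSet",
    "default_parameters",
    "rate_from_half_life",
    "mitotic_initial_state",
    "rhs",
    "jacobian",
    "load_parameters",
    "save_parameters",
]

#: State-variable names, in equation order.
VARIABLES = ("rim11", "pume6", "psok2", "ime1", "pime1", "ime2")

#: Parameters that may take the distinguished value ``inf`` (removing the
#: corresponding regulatory term in the analytic limit).
INF_CAPABLE = frozenset({"c_ime1", "c_sok2", "c1", "c2"})

# How close to zero an integrator excursion may be before it is an error
# rather than round-off (Hill terms are undefined for negative levels).
_NEG_CLAMP = -1e-9


@dataclass(frozen=True)
class ParameterSet:
    """The 19 kinetic constants of the model plus the Hill coefficient.

    Rates are per hour; the ``c_*`` half-maximum constants are
    dimensionless.  Four constants (``c_ime1``, ``c_sok2``, ``c1``,
    ``c2``) may be set to ``math.inf``, which removes the regulatory
    term they gate (evaluated as the analytic limit, never as floating
    inf/inf arithmetic).
    """

    s_ime1: float = 10.0     # Ime1 synthesis rate
    s_ime2: float = 10.0     # Ime2 synthesis rate (pUme6·pIme1 driven)
    s2_ime2: float = 3.0     # max auto-regulation-dependent Ime2 synthesis
    d_ime1: float = 1.0      # basal Ime1 degradation
    d2_ime1: float = 1.0     # max Ime2-activated Ime1 degradation
    d_pime1: float = 1.0     # pIme1 degradation
    d_ime2: float = 8.0      # Ime2 degradation (density-dependent)
    p_rim11: float = 0.01    # Rim11 phosphorylation (PKA-mediated, inactivating)
    u_rim11: float = 0.1     # Rim11 dephosphorylation (activating)
    p_ume6: float = 0.3      # Ume6 phosphorylation by Rim11
    u_ume6: float = 0.01     # Ume6 dephosphorylation
    p_sok2: float = 0.7      # Sok2 phosphorylation (PKA-mediated)
    u_sok2: float = 1.0      # Sok2 dephosphorylation
    p_ime1: float = 2.0      # Ime1 phosphorylation by Rim11
    c_sok2: float = 0.05     # half-max inhibition of Sok2 phosphorylation by Ime1
    c_ime1: float = 0.01     # half-max inhibition of Ime1 synthesis by pSok2
    c1: float = 0.01         # half-max activation of Ime1 degradation by Ime2
    c2: float = 1.4          # half-max of Ime2 auto-regulation
    c3: float = 2.0          # half-max of Ime2 degradation
    hill_n: int = 5          # Hill coefficient of Ime2 auto-regulation

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "hill_n":
                if not (isinstance(v, (int, np.integer)) and v >= 1):
                    raise ValueError(f"hill_n must be a positive integer, got {v!r}")
                continue
            v = float(v)
            if math.isnan(v):
                raise ValueError(f"parameter {f.name} is NaN")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
            if math.isinf(v) and f.name not in INF_CAPABLE:
                raise ValueError(f"parameter {f.name} cannot be infinite")
            object.__setattr__(self, f.name, v)

    def with_overrides(self, **kwargs: float) -> "ParameterSet":
        """Return a copy with the named parameters replaced."""
        unknown = set(kwargs) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: All parameter names, in declaration order (19 kinetic constants + hill_n).
PARAM_NAMES = tuple(f.name for f in fields(ParameterSet))

#: The 19 kinetic constants varied in sensitivity analysis (hill_n excluded).
KINETIC_PARAMS = tuple(n for n in PARAM_NAMES if n != "hill_n")


def default_parameters() -> ParameterSet:
    """Baseline parameter set of the published model."""
    return ParameterSet()


def rate_from_half_life(half_life: float) -> float:
    """First-order rate constant (per hour) from a half-life in hours.

    Assumes exponential decay: ``rate = ln 2 / t_half``.
    """
    if not half_life > 0:
        raise ValueError(f"half-life must be positive, got {half_life}")
    return math.log(2.0) / half_life


def mitotic_initial_state() -> np.ndarray:
    """The pre-sporulation (mitotic) state: everything 0 except pSok2 = 1.

    During vegetative growth meiosis-specific proteins are essentially
    absent while Sok2 is fully phosphorylated (repressive).
    """
    return np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# Right-hand side and Jacobian
# ---------------------------------------------------------------------------

def _inhib(c: float, x: float) -> float:
    """Inhibitory Hill factor c/(c+x); analytic limit 1 when c = inf."""
    if math.isinf(c):
        return 1.0
    return c / (c + x)


def _validate_state(state: np.ndarray) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise ValueError(f"state must have 6 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    if np.any(y < _NEG_CLAMP):
        raise ValueError(f"negative state component beyond round-off: {y}")
    return np.maximum(y, 0.0)


def _resolve(params: ParameterSet, variant) -> tuple[ParameterSet, tuple[int, ...]]:
    """Apply a model variant, returning effective parameters and the indices
    of state variables clamped to zero (deleted gene products)."""
    if variant is None:
        return params, ()
    return variant.resolve(params)


def rhs(state, params: ParameterSet, variant=None) -> np.ndarray:
    """Time derivative of the six protein levels (per hour).

    ``variant`` is an optional structural edit (gene knockout / feedback
    perturbation, see :mod:`meiosim.perturbation`); ``None`` means wild
    type.  Components of a clamped (deleted) protein are held at zero
    with zero derivative.
    """
    y = _validate_state(state)
    p, clamped = _resolve(params, variant)
    if clamped:
        y = y.copy()
        y[list(clamped)] = 0.0
    R, U, S, I, P, M = y

    dR = p.u_rim11 * (1.0 - R) - p.p_rim11 * R
    dU = p.p_ume6 * R * (1.0 - U) - p.u_ume6 * U
    dS = p.p_sok2 * _inhib(p.c_sok2, I) * (1.0 - S) - p.u_sok2 * S

    if math.isinf(p.c1):
        ime2_deg_of_ime1 = 0.0
    else:
        ime2_deg_of_ime1 = p.d2_ime1 * M * I / (p.c1 + I)
    dI = (
        p.s_ime1 * _inhib(p.c_ime1, S)
        - p.p_ime1 * R * I
        - p.d_ime1 * I
        - ime2_deg_of_ime1
    )
    dP = p.p_ime1 * R * I - p.d_pime1 * P

    n = p.hill_n
    if math.isinf(p.c2) or M == 0.0:
        auto = 0.0
    else:
        Mn = M**n
        auto = p.s2_ime2 * Mn / (p.c2**n + Mn)
    dM = p.s_ime2 * U * P + auto - p.d_ime2 * M / (p.c3 + M)

    out = np.array([dR, dU, dS, dI, dP, dM])
    if clamped:
        out[list(clamped)] = 0.0
    return out


def jacobian(state, params: ParameterSet, variant=None) -> np.ndarray:
    """Analytic 6×6 Jacobian of :func:`rhs` with respect to the state.

    Rows and columns of clamped variables are zeroed, matching the
    zero-derivative convention of :func:`rhs`.
    """
    y = _validate_state(state)
    p, clamped = _resolve(params, variant)
    if clamped:
        y = y.copy()
        y[list(clamped)] = 0.0
    R, U, S, I, P, M = y
    J = np.zeros((6, 6))

    J[0, 0] = -(p.u_rim11 + p.p_rim11)

    J[1, 0] = p.p_ume6 * (1.0 - U)
    J[1, 1] = -p.p_ume6 * R - p.u_ume6

    g = _inhib(p.c_sok2, I)
    dg = 0.0 if math.isinf(p.c_sok2) else -p.c_sok2 / (p.c_sok2 + I) ** 2
    J[2, 2] = -p.p_sok2 * g - p.u_sok2
    J[2, 3] = p.p_sok2 * (1.0 - S) * dg

    dh = 0.0 if math.isinf(p.c_ime1) else -p.c_ime1 / (p.c_ime1 + S) ** 2
    J[3, 0] = -p.p_ime1 * I
    J[3, 2] = p.s_ime1 * dh
    if math.isinf(p.c1):
        ddeg_dI = 0.0
        ddeg_dM = 0.0
    else:
        ddeg_dI = p.d2_ime1 * M * p.c1 / (p.c1 + I) ** 2
        ddeg_dM = p.d2_ime1 * I / (p.c1 + I)
    J[3, 3] = -p.p_ime1 * R - p.d_ime1 - ddeg_dI
    J[3, 5] = -ddeg_dM

    J[4, 0] = p.p_ime1 * I
    J[4, 3] = p.p_ime1 * R
    J[4, 4] = -p.d_pime1

    n = p.hill_n
    J[5, 1] = p.s_ime2 * P
    J[5, 4] = p.s_ime2 * U
    if math.isinf(p.c2):
        dauto = 0.0
    elif M == 0.0:
        # d/dM of M^n/(c2^n + M^n) at 0: 1/c2 for n=1, else 0
        dauto = p.s2_ime2 / p.c2 if n == 1 else 0.0
    else:
        cn = p.c2**n
        Mn = M**n
        dauto = p.s2_ime2 * n * cn * Mn / (M * (cn + Mn) ** 2)
    J[5, 5] = dauto - p.d_ime2 * p.c3 / (p.c3 + M) ** 2

    if clamped:
        idx = list(clamped)
        J[idx, :] = 0.0
        J[:, idx] = 0.0
    return J


# ---------------------------------------------------------------------------
# Parameter file I/O (flat key-value JSON or YAML; "inf" accepted for the
# four limit-capable constants)
# ---------------------------------------------------------------------------

def _coerce(name: str, value) -> float | int:
    if name == "hill_n":
        return int(value)
    if isinstance(value, str):
        if value.strip().lower() in {"inf", "infinite", "infinity", ".inf"}:
            return math.inf
        return float(value)
    return float(value)


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a parameter set from a flat JSON or YAML key-value file.

    Keys are the ASCII parameter names (``s_ime1``, ``d2_ime1``, …);
    missing keys keep their baseline value; the string ``"inf"`` is
    accepted for the four limit-capable constants.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    unknown = set(raw) - set(PARAM_NAMES)
    if unknown:
        raise KeyError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    values = {k: _coerce(k, v) for k, v in raw.items()}
    return default_parameters().with_overrides(**values)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as flat JSON (``inf`` serialized as a string)."""
    d = {
        k: ("inf" if isinstance(v, float) and math.isinf(v) else v)
        for k, v in params.as_dict().items()
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")
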