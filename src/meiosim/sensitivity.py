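"""Multi-parametric sensitivity analysis (MPSA).

All 19 kinetic constants are varied simultaneously over one order of
magnitude around baseline via Latin hypercube sampling with uniform
marginals.  For each random parameter set the model is integrated from
the mitotic state, and a per-variable objective — the sum of squared
errors of the time course against the baseline time course on a shared
grid — splits the samples into "acceptable" (objective below the mean
objective) and "unacceptable" classes.  The sensitivity of a parameter
for a variable is the Kolmogorov–Smirnov distance between the
class-conditional empirical distributions of that parameter's sampled
values: a parameter whose value strongly determines whether the output
stays near baseline separates the classes and scores near 1, an
irrelevant parameter scores near the KS null level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, qmc

from .model_core import KINETIC_PARAMS, VARIABLES, ParameterSet
from .perturbation import ModelVariant, wild_type
from .simulation import Trajectory, integrate

__all__ = [
    "SampleDesign",
    "SensitivityReport",
    "lhs_sample",
    "objective_sse",
    "ks_distance",
    "run_mpsa",
]


@dataclass(frozen=True)
class SampleDesign:
    """Latin hypercube design for the 19 kinetic constants."""

    n_samples: int = 5000
    range_factor: float = 10.0   # sampled range is [base/f, base·f]
    seed: int = 0
    log_uniform: bool = False    # linear-scale uniform marginals by default
    parameters: tuple[str, ...] = KINETIC_PARAMS

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not self.range_factor > 1:
            raise ValueError("range_factor must be > 1")
        bad = set(self.parameters) - set(KINETIC_PARAMS)
        if bad:
            raise ValueError(f"unknown parameter(s): {sorted(bad)}")


@dataclass(frozen=True)
class SensitivityReport:
    """KS sensitivities per (parameter, variable), with audit trail."""

    sensitivities: pd.DataFrame   # index = parameters, columns = variables
    design: SampleDesign
    objectives: pd.DataFrame      # per-sample objective per variable
    samples: pd.DataFrame         # the sampled parameter matrix

    def top(self, variable: str, k: int = 3) -> list[str]:
        """The ``k`` most sensitive parameters for one variable."""
        col = self.sensitivities[variable].dropna()
        return list(col.sort_values(ascending=False).index[:k])


def lhs_sample(design: SampleDesign, baselines: ParameterSet | None = None) -> pd.DataFrame:
    """Latin hypercube sample of the designed parameters.

    Each column holds exactly one value per equal-probability stratum of
    Uniform[baseline/range_factor, baseline·range_factor] (on the log
    scale if ``design.log_uniform``); rows are full parameter sets.
    Reproducible under ``design.seed``.
    """
    if baselines is None:
        baselines = ParameterSet()
    base = np.array([getattr(baselines, n) for n in design.parameters])
    if np.any(base <= 0):
        zero = [n for n, b in zip(design.parameters, base) if b <= 0]
        raise ValueError(
            f"baseline of {zero} is not positive; the sampling range degenerates"
        )
    sampler = qmc.LatinHypercube(d=len(design.parameters), seed=design.seed)
    u = sampler.random(design.n_samples)
    lo, hi = base / design.range_factor, base * design.range_factor
    if design.log_uniform:
        vals = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    else:
        vals = lo + u * (hi - lo)
    return pd.DataFrame(vals, columns=list(design.parameters))


def objective_sse(
    traj_random: Trajectory, traj_baseline: Trajectory, variable: str
) -> float:
    """Sum of squared errors between two time courses of one variable.

    A diverged (truncated) random trajectory scores ``inf`` — it can
    never be "acceptable".
    """
    if traj_random.diverged:
        return float("inf")
    if len(traj_random.t) != len(traj_baseline.t) or not np.allclose(
        traj_random.t, traj_baseline.t
    ):
        raise ValueError("trajectories must share a time grid")
    d = traj_random.series(variable) - traj_baseline.series(variable)
    return float(np.dot(d, d))


def ks_distance(values_acceptable, values_unacceptable) -> float:
    """Sup-norm distance between two empirical CDFs (two-sample KS statistic)."""
    a = np.asarray(values_acceptable, dtype=float)
    b = np.asarray(values_unacceptable, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    return float(ks_2samp(a, b).statistic)


def run_mpsa(
    variant: ModelVariant | None = None,
    params: ParameterSet | None = None,
    design: SampleDesign | None = None,
    t_end: float = 24.0,
    n_grid: int = 97,
) -> SensitivityReport:
    """Full MPSA: sample, simulate, classify, and score all parameters.

    Each sampled parameter set is integrated from the mitotic state on a
    uniform grid over [0, t_end].  Classification and KS scoring are
    done per variable, so each variable has its own acceptable /
    unacceptable split.  Samples whose integration diverges or fails
    receive an infinite objective and are always unacceptable; the mean
    threshold is computed over the finite objectives.
    """
    if params is None:
        params = ParameterSet()
    if design is None:
        design = SampleDesign()
    if variant is None:
        variant = wild_type()

    samples = lhs_sample(design, params)
    baseline = integrate(variant, params, t_end=t_end, n_points=n_grid)

    obj = np.full((design.n_samples, len(VARIABLES)), np.inf)
    for i in range(design.n_samples):
        p_i = params.with_overrides(**samples.iloc[i].to_dict())
        try:
            traj = integrate(variant, p_i, t_end=t_end, n_points=n_grid)
        except (RuntimeError, ValueError):
            continue  # failed integration: objective stays inf
        for j, v in enumerate(VARIABLES):
            obj[i, j] = objective_sse(traj, baseline, v)

    sens = pd.DataFrame(
        np.nan, index=list(design.parameters), columns=list(VARIABLES)
    )
    for j, v in enumerate(VARIABLES):
        col = obj[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            warnings.warn(f"no finite objectives for {v}; sensitivities undefined")
            continue
        threshold = col[finite].mean()
        acceptable = col < threshold       # inf objectives are never acceptable
        if acceptable.all() or not acceptable.any():
            warnings.warn(f"degenerate classification for {v}; sensitivities undefined")
            continue
        for name in design.parameters:
            x = samples[name].to_numpy()
            sens.loc[name, v] = ks_distance(x[acceptable], x[~acceptable])

    objectives = pd.DataFrame(obj, columns=list(VARIABLES))
    return SensitivityReport(
        sensitivities=sens, design=design, objectives=objectives, samples=samples
    )
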