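"""Genotype-panel validation against sporulation-screen ratios.

The model's readout for sporulation efficiency is the steady-state Ime2
level, simulated for wild type and each of the five single-gene
deletions.  A genome-wide deletion screen provides one experimental
sporulation/pre-sporulation ratio per genotype; the published
comparison correlates those ratios with the simulated Ime2 column
(Pearson r = 0.85 on the real screen, which is not bundled here — a
two-column TSV loader accepts it when available).

For self-contained testing, :func:`synth_screen` generates a synthetic
screen: a positive affine link from simulated Ime2 to the ratio, with
multiplicative log-normal noise (ratios are positive, fold-type
quantities).  With zero noise the correlation is exactly 1 by
construction; the noise level controls how much of that signal
survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import ParameterSet
from .perturbation import GENES, knockout, wild_type
from .simulation import find_steady_state

__all__ = [
    "GENOTYPES",
    "genotype_panel",
    "synth_screen",
    "pearson",
    "validate_against",
    "load_screen",
]

#: Genotype ids: wild type plus lowercase single-deletion names.
GENOTYPES = ("WT", "rim11", "ume6", "sok2", "ime1", "ime2")


def genotype_panel(params: ParameterSet | None = None) -> pd.DataFrame:
    """Steady-state Ime2 for wild type and the five single knockouts.

    Returns a DataFrame with columns ``genotype`` and ``ime2_steady``.
    The four sporulation-deficient deletions (rim11, ume6, ime1, ime2)
    have Ime2 exactly 0; sok2 deletion (sporulation-proficient) sits
    above wild type.
    """
    if params is None:
        params = ParameterSet()
    rows = []
    for genotype in GENOTYPES:
        variant = wild_type()
        if genotype != "WT":
            variant = knockout(variant, genotype.upper())
        ss, converged = find_steady_state(variant, params)
        if not converged:
            raise RuntimeError(f"steady state did not converge for {genotype}")
        rows.append({"genotype": genotype, "ime2_steady": float(ss[5])})
    return pd.DataFrame(rows)


def synth_screen(
    panel: pd.DataFrame,
    a: float = 1.0,
    b: float = 0.1,
    sigma: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic sporulation/pre-sporulation ratios linked to the panel.

    ``ratio = (a·ime2 + b) · exp(eps)`` with ``eps ~ N(0, sigma²)``
    i.i.d. per genotype.  ``a`` scales the signal, ``b > 0`` keeps
    zero-Ime2 genotypes at a positive floor (screens report small but
    non-zero ratios for deficient strains), and ``sigma`` is the
    log-scale noise standard deviation.  With ``sigma = 0`` the link is
    strictly monotone in Ime2.
    """
    if not a > 0:
        raise ValueError("link scale a must be > 0")
    if b < 0:
        raise ValueError("link offset b must be >= 0")
    if sigma < 0:
        raise ValueError("noise sd sigma must be >= 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=len(panel))
    ratio = (a * panel["ime2_steady"].to_numpy() + b) * np.exp(eps)
    return pd.DataFrame({"genotype": panel["genotype"], "ratio": ratio})


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    p_value: float
    n: int
    #: Whether the correlation reaches the strength reported for the
    #: real deletion screen (r >= 0.85 at p <= 0.05).
    meets_reported_strength: bool


def validate_against(screen: pd.DataFrame, panel: pd.DataFrame) -> CorrelationReport:
    """Correlate screen ratios with simulated steady-state Ime2.

    ``screen`` must provide a ``ratio`` for every genotype in the
    panel (synthetic or user-supplied); rows are joined on
    ``genotype``.
    """
    missing = set(panel["genotype"]) - set(screen["genotype"])
    if missing:
        raise ValueError(f"screen is missing genotype(s): {sorted(missing)}")
    merged = panel.merge(screen, on="genotype", how="inner")
    r, p = pearson(merged["ratio"], merged["ime2_steady"])
    return CorrelationReport(
        r=r, p_value=p, n=len(merged),
        meets_reported_strength=bool(r >= 0.85 and p <= 0.05),
    )


def load_screen(path: str | Path) -> pd.DataFrame:
    """Read a two-column (genotype, ratio) TSV of experimental ratios."""
    df = pd.read_csv(path, sep="\t")
    expected = {"genotype", "ratio"}
    if not expected <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    if (df["ratio"] <= 0).any():
        raise ValueError(f"{path}: ratios must be positive")
    return df[["genotype", "ratio"]]
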