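"""Model variants: gene knockouts and feedback-loop perturbations.

A :class:`ModelVariant` is an immutable recipe of structural edits to
the wild-type model:

* **knockouts** — virtual deletion of any of the five modeled genes.
  A deletion removes the gene product permanently, realized by clamping
  the protein's state variables to zero (with zero derivative) and
  zeroing its synthesis rates.
* **feedback modes** — up-/down-regulation or deletion of each of the
  three feedback loops, expressed as the published parameter overrides
  (deletion sets a half-maximum constant to ``inf`` or a rate to 0).
* **overrides** — arbitrary single-parameter replacements, used by the
  bifurcation scans and sensitivity sampling.

Variants are resolved lazily: :meth:`ModelVariant.resolve` turns the
recipe into an effective :class:`~meiosim.model_core.ParameterSet` plus
the tuple of clamped state indices, which is what the right-hand side
consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .model_core import PARAM_NAMES, INF_CAPABLE, VARIABLES, ParameterSet

__all__ = [
    "GENES",
    "LOOPS",
    "MODES",
    "ModelVariant",
    "wild_type",
    "knockout",
    "set_feedback",
    "override",
]

#: The five modeled genes (deletable).
GENES = ("RIM11", "UME6", "SOK2", "IME1", "IME2")

#: Feedback-loop identifiers.
LOOPS = (
    "SOK2_IME1_double_negative",
    "IME2_IME1_negative",
    "IME2_auto_positive",
)

MODES = ("baseline", "increased", "decreased", "deleted")

# State indices clamped to zero and synthesis rates zeroed per deletion.
# Rim11/Ume6/Sok2 are conserved pools, so deleting the gene empties the
# pool: the phosphoform tracked by the model is clamped at 0.  IME1 and
# IME2 deletions additionally lose their synthesis terms.
_KO_CLAMP = {
    "RIM11": (0,),
    "UME6": (1,),
    "SOK2": (2,),
    "IME1": (3, 4),
    "IME2": (5,),
}
_KO_PARAMS = {
    "RIM11": {},
    "UME6": {},
    "SOK2": {},
    "IME1": {"s_ime1": 0.0},
    "IME2": {"s_ime2": 0.0, "s2_ime2": 0.0},
}

# Published perturbation values per loop, mode and arm.  The
# double-negative loop has two individually addressable arms
# (pSok2 ⊣ Ime1 via c_ime1; Ime1 ⊣ pSok2 via c_sok2); "both" applies
# the simultaneous variation.
_FEEDBACK = {
    "SOK2_IME1_double_negative": {
        "deleted": {"c_ime1": math.inf, "c_sok2": math.inf},
        "decreased": {"c_ime1": 0.1, "c_sok2": 0.5},
        "increased": {"c_ime1": 0.001, "c_sok2": 0.005},
    },
    "IME2_IME1_negative": {
        "deleted": {"d2_ime1": 0.0, "c1": math.inf},
        "decreased": {"d2_ime1": 0.1, "c1": 0.1},
        "increased": {"d2_ime1": 10.0, "c1": 0.001},
    },
    "IME2_auto_positive": {
        "deleted": {"s2_ime2": 0.0, "c2": math.inf},
        "decreased": {"s2_ime2": 0.3, "c2": 14.0},
        "increased": {"s2_ime2": 30.0, "c2": 0.14},
    },
}

_ARMS = {
    "SOK2_IME1_double_negative": {"c_ime1": ("c_ime1",), "c_sok2": ("c_sok2",)},
    "IME2_IME1_negative": {"d2_ime1": ("d2_ime1",), "c1": ("c1",)},
    "IME2_auto_positive": {"s2_ime2": ("s2_ime2",), "c2": ("c2",)},
}


def _check_value(name: str, value: float) -> float:
    if name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {name!r}")
    if name == "hill_n":
        v = int(value)
        if v < 1:
            raise ValueError("hill_n must be >= 1")
        return v
    if isinstance(value, str):
        if value.strip().lower() in {"inf", "infinite", "infinity"}:
            value = math.inf
        else:
            value = float(value)
    value = float(value)
    if math.isnan(value) or value < 0:
        raise ValueError(f"parameter {name} must be >= 0, got {value}")
    if math.isinf(value) and name not in INF_CAPABLE:
        raise ValueError(f"parameter {name} cannot be infinite")
    return value


@dataclass(frozen=True)
class ModelVariant:
    """Structural edits to the wild-type model (immutable, composable)."""

    knockouts: frozenset[str] = frozenset()
    feedback_modes: Mapping[str, str] = field(
        default_factory=lambda: MappingProxyType({})
    )
    overrides: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({})
    )

    def __post_init__(self) -> None:
        bad = set(self.knockouts) - set(GENES)
        if bad:
            raise ValueError(f"unknown gene(s): {sorted(bad)}")
        for loop, mode in self.feedback_modes.items():
            if loop not in LOOPS:
                raise ValueError(f"unknown feedback loop {loop!r}")
            if mode not in MODES:
                raise ValueError(f"unknown feedback mode {mode!r}")
        for name, value in self.overrides.items():
            _check_value(name, value)

    @property
    def is_wild_type(self) -> bool:
        return (
            not self.knockouts
            and all(m == "baseline" for m in self.feedback_modes.values())
            and not self.overrides
        )

    def resolve(self, params: ParameterSet) -> tuple[ParameterSet, tuple[int, ...]]:
        """Effective parameters and clamped state indices for this variant.

        Precedence: feedback-mode values, then knockout synthesis zeroing,
        then explicit overrides (later edits shadow earlier ones).
        """
        edits: dict[str, float] = {}
        for loop, mode in self.feedback_modes.items():
            if mode == "baseline":
                continue
            edits.update(_FEEDBACK[loop][mode])
        clamped: set[int] = set()
        for gene in self.knockouts:
            clamped.update(_KO_CLAMP[gene])
            edits.update(_KO_PARAMS[gene])
        edits.update(self.overrides)
        eff = params.with_overrides(**edits) if edits else params
        return eff, tuple(sorted(clamped))


def wild_type() -> ModelVariant:
    """The unperturbed model."""
    return ModelVariant()


def knockout(variant: ModelVariant, gene: str) -> ModelVariant:
    """Add a virtual single-gene deletion to ``variant``."""
    if gene not in GENES:
        raise ValueError(f"unknown gene {gene!r}; expected one of {GENES}")
    return ModelVariant(
        knockouts=variant.knockouts | {gene},
        feedback_modes=variant.feedback_modes,
        overrides=variant.overrides,
    )


def set_feedback(
    variant: ModelVariant, loop: str, mode: str, arm: str | None = None
) -> ModelVariant:
    """Perturb one feedback loop to a published mode.

    ``arm`` restricts the perturbation to a single parameter arm of the
    loop (e.g. only ``c_ime1`` of the double-negative loop, as in the
    single-arm simulation experiments); ``None`` varies all arms
    simultaneously.
    """
    if loop not in LOOPS:
        raise ValueError(f"unknown feedback loop {loop!r}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "baseline":
        touched = set(_FEEDBACK[loop][mode])
        conflicts = {
            k
            for k in touched & set(variant.overrides)
            if variant.overrides[k] != _FEEDBACK[loop][mode][k]
        }
        if conflicts:
            raise ValueError(
                f"feedback mode {loop}:{mode} conflicts with explicit "
                f"override(s) of {sorted(conflicts)}"
            )
    if arm is None:
        modes = dict(variant.feedback_modes)
        modes[loop] = mode
        return ModelVariant(
            knockouts=variant.knockouts,
            feedback_modes=MappingProxyType(modes),
            overrides=variant.overrides,
        )
    if arm not in _ARMS[loop]:
        raise ValueError(
            f"unknown arm {arm!r} for loop {loop}; expected one of "
            f"{tuple(_ARMS[loop])}"
        )
    if mode == "baseline":
        return variant
    edits = {
        k: v for k, v in _FEEDBACK[loop][mode].items() if k in _ARMS[loop][arm]
    }
    out = variant
    for name, value in edits.items():
        out = override(out, name, value)
    return out


def override(variant: ModelVariant, name: str, value) -> ModelVariant:
    """Record a single-parameter override; later overrides shadow earlier.

    ``value`` may be the string ``"inf"`` (or ``math.inf``) for the four
    limit-capable half-maximum constants.
    """
    v = _check_value(name, value)
    merged = dict(variant.overrides)
    merged[name] = v  # shadowing: last value wins
    return ModelVariant(
        knockouts=variant.knockouts,
        feedback_modes=variant.feedback_modes,
        overrides=MappingProxyType(merged),
    )
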