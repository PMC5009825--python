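"""Elementary kinetic rate laws and the Hill-type leukemic-influence modifier.

Every cellular process in the model (proliferation, death, migration,
differentiation, quiescence transitions) is assembled from one of five
elementary rate laws evaluated on a driving cell count X, optionally
multiplied by a leukemic modifier K(L) that encodes how the leukemic burden
L in the same tissue suppresses or stimulates the process:

    zero_order              r = k
    first_order             r = k * X
    exponential_saturating  r = k * (1 - exp(-X / theta))
    michaelis_menten        r = vmax * X / (km + X)
    hill                    r = vmax * X**h / (k**h + X**h)

    suppressive  K(L) = 1 / (1 + (c * L)**h_L),  c = 1/theta_L
    stimulative  K(L) = 1 + beta * L**h_L / (theta_L**h_L + L**h_L)

All rates are nonnegative for X >= 0, K(0) = 1 exactly for every modifier
(the disease-free limit), and hill with h = 1 reduces to michaelis_menten
with km = k.  The suppressive modifier is written in terms of the inverse
threshold c so that setting the coupling strength c to zero recovers K == 1
bit-exactly, which is how the leukemia-free control model is obtained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FORM_KINDS",
    "RateForm",
    "LeukemicModifier",
    "eval_rate",
    "eval_modifier",
    "modified_rate",
    "form_param_names",
    "form_scale_param",
]

FORM_KINDS = (
    "zero_order",
    "first_order",
    "exponential_saturating",
    "michaelis_menten",
    "hill",
)

#: parameter names, in canonical order, for each rate-law kind
_FORM_PARAMS = {
    "zero_order": ("k",),
    "first_order": ("k",),
    "exponential_saturating": ("k", "theta"),
    "michaelis_menten": ("vmax", "km"),
    "hill": ("vmax", "k", "h"),
}

#: the multiplicative scale parameter of each kind (used by the homeostatic
#: balance closure in :mod:`hemakin.model`)
_FORM_SCALE = {
    "zero_order": "k",
    "first_order": "k",
    "exponential_saturating": "k",
    "michaelis_menten": "vmax",
    "hill": "vmax",
}


def form_param_names(kind: str) -> tuple[str, ...]:
    try:
        return _FORM_PARAMS[kind]
    except KeyError:
        raise ValueError(f"unknown rate-form kind {kind!r}") from None


def form_scale_param(kind: str) -> str:
    return _FORM_SCALE[kind]


@dataclass(frozen=True)
class RateForm:
    """A concrete elementary rate law: a kind plus named nonnegative parameters."""

    kind: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = form_param_names(self.kind)
        missing = [n for n in names if n not in self.params]
        if missing:
            raise ValueError(f"{self.kind} form missing parameters {missing}")
        for name, value in self.params.items():
            if name not in names:
                raise ValueError(f"{self.kind} form has no parameter {name!r}")
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{self.kind}.{name} must be finite and >= 0, got {value}")
        if self.kind == "hill" and self.params["h"] < 1:
            raise ValueError("hill coefficient h must be >= 1")
        # saturation scales must be strictly positive for the form to be evaluable
        for scale in ("theta", "km"):
            if scale in names and self.params[scale] <= 0:
                raise ValueError(f"{self.kind}.{scale} must be > 0")
        if self.kind == "hill" and self.params["k"] <= 0:
            raise ValueError("hill.k must be > 0")


@dataclass(frozen=True)
class LeukemicModifier:
    """Hill-form leukemic influence K(L) on a process rate.

    direction: "suppressive", "stimulative", or "none".
    Suppressive modifiers carry (inv_theta_L, h_L); stimulative carry
    (beta, theta_L, h_L).  inv_theta_L and beta are the coupling strengths:
    setting them to 0 yields K == 1 for every L.
    """

    direction: str = "none"
    beta: float = 0.0
    inv_theta_L: float = 0.0
    theta_L: float = 1.0
    h_L: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("suppressive", "stimulative", "none"):
            raise ValueError(f"unknown modifier direction {self.direction!r}")
        if self.h_L < 1:
            raise ValueError("modifier coefficient h_L must be >= 1")
        if self.beta < 0 or self.inv_theta_L < 0:
            raise ValueError("modifier coupling strengths must be >= 0")
        if self.direction == "stimulative" and self.theta_L <= 0:
            raise ValueError("stimulative modifier requires theta_L > 0")


def eval_rate(form: RateForm, x: float) -> float:
    """Evaluate an elementary rate law at cell count ``x`` (cells/day)."""
    if not (x >= 0):
        raise ValueError(f"cell count must be >= 0, got {x}")
    p = form.params
    kind = form.kind
    if kind == "zero_order":
        return p["k"]
    if kind == "first_order":
        return p["k"] * x
    if kind == "exponential_saturating":
        return p["k"] * -math.expm1(-x / p["theta"])
    if kind == "michaelis_menten":
        if x == 0.0:
            return 0.0
        return p["vmax"] * x / (p["km"] + x)
    if kind == "hill":
        if x == 0.0:
            return 0.0
        ratio = (x / p["k"]) ** p["h"]
        return p["vmax"] * ratio / (1.0 + ratio)
    raise ValueError(f"unknown rate-form kind {kind!r}")


def eval_modifier(mod: LeukemicModifier, L: float) -> float:
    """Evaluate the leukemic-influence multiplier K at leukemic burden ``L``."""
    if not (L >= 0):
        raise ValueError(f"leukemic burden must be >= 0, got {L}")
    if mod.direction == "none":
        return 1.0
    if mod.direction == "suppressive":
        u = mod.inv_theta_L * L
        if u == 0.0:
            return 1.0
        return 1.0 / (1.0 + u**mod.h_L)
    # stimulative
    if L == 0.0 or mod.beta == 0.0:
        return 1.0
    ratio = (L / mod.theta_L) ** mod.h_L
    return 1.0 + mod.beta * ratio / (1.0 + ratio)


def modified_rate(form: RateForm, mod: LeukemicModifier, x: float, L: float) -> float:
    """Base rate at ``x`` multiplied by the leukemic modifier at ``L``."""
    return eval_rate(form, x) * eval_modifier(mod, L)
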