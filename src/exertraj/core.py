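"""Trajectory data model and the four stimulus-response model families.

Four families describe a Borg rating trajectory as a function of the
fraction of maximal work capacity ``x`` in (0, 1]:

* ``P``  (power):            a + b2 * x**d
* ``D``  (delay):            a + b1 * max(x - c, 0)
* ``PD`` (power-delay):      a + b2 * max(x - c, 0)**d
* ``QD`` (quadratic-delay):  a + b1 * max(x - c, 0) + b2 * max(x - c, 0)**2

The delayed term is defined to be exactly 0 whenever ``x <= c`` for every
``d >= 0``, so predictions are flat (equal to the intercept ``a``) before
the delay, including the ``0**0`` corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "ModelFamily",
    "FAMILIES",
    "ParamSet",
    "SubjectTrajectory",
    "LikelihoodResult",
    "get_family",
    "predict_rating",
    "sse_and_loglik",
    "gaussian_profile_loglik",
]

RATING_MIN = 0.0
RATING_MAX = 10.0


@dataclass(frozen=True)
class ModelFamily:
    """One of the four model families with its coefficient bookkeeping."""

    name: str
    k: int
    parameter_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.k != len(self.parameter_names):
            raise ValueError(
                f"family {self.name}: k={self.k} != "
                f"{len(self.parameter_names)} parameter names"
            )

    @property
    def has_delay(self) -> bool:
        return "c" in self.parameter_names

    @property
    def has_exponent(self) -> bool:
        return "d" in self.parameter_names

    @property
    def linear_names(self) -> tuple[str, ...]:
        """Coefficients that enter linearly given the nonlinear ones."""
        return tuple(p for p in self.parameter_names if p in ("a", "b1", "b2"))

    @property
    def nonlinear_names(self) -> tuple[str, ...]:
        return tuple(p for p in self.parameter_names if p in ("c", "d"))


FAMILIES: dict[str, ModelFamily] = {
    "P": ModelFamily("P", 3, ("a", "b2", "d")),
    "D": ModelFamily("D", 3, ("a", "b1", "c")),
    "PD": ModelFamily("PD", 4, ("a", "b2", "c", "d")),
    "QD": ModelFamily("QD", 4, ("a", "b1", "b2", "c")),
}


def get_family(family: "str | ModelFamily") -> ModelFamily:
    if isinstance(family, ModelFamily):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown model family {family!r}; expected one of {sorted(FAMILIES)}"
        ) from None


@dataclass
class ParamSet:
    """Parameter values for one family; unused fields stay ``None``.

    ``sigma2`` is the residual variance of the Gaussian error model and is
    not counted among the ``k`` coefficients of a family.
    """

    a: Optional[float] = None
    b1: Optional[float] = None
    b2: Optional[float] = None
    c: Optional[float] = None
    d: Optional[float] = None
    sigma2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.d is not None and self.d < 0:
            raise ValueError(f"exponent d must be >= 0, got {self.d}")
        if self.sigma2 is not None and self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")

    def require(self, family: "str | ModelFamily") -> dict[str, float]:
        """Return the family's parameters, rejecting missing ones."""
        fam = get_family(family)
        out: dict[str, float] = {}
        for name in fam.parameter_names:
            val = getattr(self, name)
            if val is None:
                raise ValueError(
                    f"family {fam.name} requires parameter {name!r}"
                )
            out[name] = float(val)
        return out

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "a": self.a, "b1": self.b1, "b2": self.b2,
            "c": self.c, "d": self.d, "sigma2": self.sigma2,
        }


@dataclass
class SubjectTrajectory:
    """One subject's ratings against fractions of maximal work capacity."""

    subject_id: str
    x: np.ndarray
    y: np.ndarray
    covariates: Mapping[str, object] = field(default_factory=dict)
    #: noiseless model-curve fixtures may overshoot the 0-10 scale slightly;
    #: set False to skip the rating-range check (structural checks remain)
    validate_range: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if len(self.x) != len(self.y):
            raise ValueError(
                f"subject {self.subject_id}: len(x)={len(self.x)} != len(y)={len(self.y)}"
            )
        if len(self.x) < 2:
            raise ValueError(f"subject {self.subject_id}: need at least 2 observations")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError(f"subject {self.subject_id}: x must be strictly increasing")
        if self.x[0] <= 0 or self.x[-1] > 1 + 1e-9:
            raise ValueError(
                f"subject {self.subject_id}: work fractions must lie in (0, 1]"
            )
        if self.validate_range and (
            np.any(self.y < RATING_MIN - 1e-9)
            or np.any(self.y > RATING_MAX + 1e-9)
        ):
            raise ValueError(
                f"subject {self.subject_id}: ratings must lie in "
                f"[{RATING_MIN}, {RATING_MAX}]"
            )

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n_distinct_ratings(self) -> int:
        return len(np.unique(self.y))

    @property
    def max_rating(self) -> float:
        return float(np.max(self.y))


def delayed_term(x: np.ndarray, c: float, d: float = 1.0) -> np.ndarray:
    """``max(x - c, 0)**d`` with the convention that the term is 0 for x <= c.

    numpy evaluates ``0.0**0.0`` as 1; the flat-before-delay convention
    requires 0 there instead, for every d >= 0.
    """
    z = np.maximum(np.asarray(x, dtype=float) - c, 0.0)
    if d == 1.0:
        return z
    return np.where(z > 0.0, np.power(z, d, where=z > 0.0, out=np.zeros_like(z)), 0.0)


def predict_rating(
    family: "str | ModelFamily",
    params: ParamSet,
    x: "float | Sequence[float] | np.ndarray",
) -> "float | np.ndarray":
    """Evaluate a family's mean response at work fraction(s) ``x``."""
    fam = get_family(family)
    p = params.require(fam)
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    if np.any(xa < -1e-12) or np.any(xa > 1 + 1e-9):
        raise ValueError("work fractions must lie in [0, 1]")

    if fam.name == "P":
        term = np.where(xa > 0.0, np.power(xa, p["d"],
                                           where=xa > 0.0,
                                           out=np.zeros_like(xa)), 0.0)
        out = p["a"] + p["b2"] * term
    elif fam.name == "D":
        out = p["a"] + p["b1"] * delayed_term(xa, p["c"])
    elif fam.name == "PD":
        out = p["a"] + p["b2"] * delayed_term(xa, p["c"], p["d"])
    else:  # QD
        z = delayed_term(xa, p["c"])
        out = p["a"] + p["b1"] * z + p["b2"] * z * z
    return float(out[0]) if scalar else out


class LikelihoodResult(NamedTuple):
    sse: float
    loglik: float
    perfect_fit: bool


def gaussian_profile_loglik(sse: float, n: int) -> "tuple[float, bool]":
    """Maximized Gaussian log-likelihood at the profile MLE variance SSE/n.

    Returns ``(loglik, perfect_fit)``; a zero SSE yields an infinite
    log-likelihood sentinel with the degenerate flag set.
    """
    if n <= 0:
        raise ValueError("need at least one observation")
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if sse <= 0.0:
        return math.inf, True
    sigma2_hat = sse / n
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2_hat) + 1.0), False


def sse_and_loglik(
    traj: SubjectTrajectory,
    family: "str | ModelFamily",
    params: ParamSet,
) -> LikelihoodResult:
    """Sum of squared residuals and profile-MLE Gaussian log-likelihood."""
    if traj.n == 0:
        raise ValueError("empty trajectory")
    yhat = predict_rating(family, params, traj.x)
    resid = traj.y - yhat
    sse = float(resid @ resid)
    loglik, perfect = gaussian_profile_loglik(sse, traj.n)
    return LikelihoodResult(sse=sse, loglik=loglik, perfect_fit=perfect)
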