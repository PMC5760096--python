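"""Hill-equation input nonlinearity: transform, inverse, and parameter sampling.

Each input channel of the NARX model is passed through a static Hill function

    f(u; n, K) = u**n / (u**n + K**n)

before entering the linear ARX stage.  ``K`` is the half-maximal input (EC50)
on the normalized [0, 1] scale and ``n`` the Hill coefficient: n near 1 gives
a graded dose-response, large n a switch-like response around K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["HillParams", "hill_transform", "hill_inverse", "sample_params"]

_CLAMP_EPS = 1e-9


@dataclass(frozen=True)
class HillParams:
    """Hill coefficient ``n`` (>= 1) and EC50 ``K`` with K**n in [0.001, 1]."""

    n: float
    K: float

    def __post_init__(self) -> None:
        if not (self.n >= 1):
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")
        if not (self.K > 0):
            raise ValueError(f"EC50 K must be positive, got {self.K}")


def hill_transform(u, params: HillParams):
    """Apply f(u) = u**n / (u**n + K**n); scalar or array, u >= 0.

    Evaluated as 1 / (1 + exp(n * (log K - log u))), which stays finite for
    the large Hill coefficients (n up to 100) the parameter search visits.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("Hill transform requires u >= 0")
    out = np.zeros_like(u)
    pos = u > 0
    with np.errstate(over="ignore"):
        out[pos] = 1.0 / (
            1.0 + np.exp(params.n * (math.log(params.K) - np.log(u[pos])))
        )
    return out if out.ndim else float(out)


def hill_inverse(x, params: HillParams):
    """Invert the Hill function: u = K * (x / (1 - x))**(1/n).

    Values outside [0, 1) — which recovered matrix entries can slightly
    produce — are clamped into range with a warning rather than rejected,
    keeping the recovery loop total.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0) or np.any(x >= 1):
        warnings.warn(
            "hill_inverse input outside [0, 1); clamping", RuntimeWarning, stacklevel=2
        )
        x = np.clip(x, 0.0, 1.0 - _CLAMP_EPS)
    with np.errstate(divide="ignore"):
        u = params.K * np.power(x / (1.0 - x), 1.0 / params.n)
    return float(u[0]) if scalar else u


def sample_params(rng: np.random.Generator, phase: str = "search") -> HillParams:
    """Draw Hill parameters for one restart of the identification search.

    ``phase="init"``: n = 1 exactly and K**n = K ~ Uniform(0, 1] — the
    starting point of each restart.  ``phase="search"``: n ~ Uniform(1, 100]
    and K**n ~ Uniform[0.001, 1], then K = (K**n)**(1/n); the search draws
    K**n (not K) uniformly, so small EC50s are reachable at large n.
    """
    if phase == "init":
        k = 1.0 - rng.random()  # (0, 1]
        return HillParams(n=1.0, K=k)
    if phase == "search":
        n = 1.0 + rng.random() * 99.0
        if n == 1.0:  # open at 1
            n = np.nextafter(1.0, 2.0)
        kn = rng.uniform(0.001, 1.0)
        return HillParams(n=n, K=kn ** (1.0 / n))
    raise ValueError(f"unknown phase {phase!r}")
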