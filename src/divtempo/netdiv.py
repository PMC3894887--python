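"""Magallon-Sanderson whole-clade net diversification estimators.

Given the number of extant species ``n``, a clade age ``t`` (stem or crown)
and an assumed relative extinction fraction ``epsilon = mu/lambda``, the
method-of-moments estimator inverts the expected standing diversity of a
birth-death process.  At ``epsilon = 0`` the estimators collapse to
``ln(n)/t`` (stem) and ``ln(n/2)/t`` (crown); higher assumed extinction
always lowers the inferred net rate.

Because the rate is proportional to ``1/t`` for fixed (n, epsilon), the age
implied by a printed rate is recovered exactly by :func:`ms_age_from_rate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetDivEstimate", "ms_rate", "ms_age_from_rate"]


@dataclass(frozen=True)
class NetDivEstimate:
    r: float  # net diversification rate, sp/Myr
    epsilon: float
    mode: str  # "stem" | "crown"
    n: int
    t: float


def _log_numerator(n: int, epsilon: float, mode: str) -> float:
    """The age-free part of the estimator: r = numerator / t."""
    if mode == "stem":
        return float(np.log(n * (1.0 - epsilon) + epsilon))
    if mode == "crown":
        inner = (
            0.5 * n * (1.0 - epsilon**2)
            + 2.0 * epsilon
            + 0.5
            * (1.0 - epsilon)
            * np.sqrt(n * (n * epsilon**2 - 8.0 * epsilon + 2.0 * n * epsilon + n))
        )
        return float(np.log(inner) - np.log(2.0))
    raise ValueError(f"mode must be 'stem' or 'crown', got {mode!r}")


def _check(n: int, epsilon: float) -> None:
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")


def ms_rate(n: int, t: float, epsilon: float = 0.0, mode: str = "crown") -> NetDivEstimate:
    """Whole-clade net diversification rate for n species of age t Myr."""
    _check(n, epsilon)
    if t <= 0:
        raise ValueError("clade age t must be > 0")
    r = _log_numerator(n, epsilon, mode) / t
    return NetDivEstimate(r=r, epsilon=epsilon, mode=mode, n=n, t=t)


def ms_age_from_rate(n: int, r: float, epsilon: float = 0.0, mode: str = "crown") -> float:
    """Clade age t such that ``ms_rate(n, t, epsilon, mode).r == r`` (exact)."""
    _check(n, epsilon)
    if r <= 0:
        raise ValueError("rate r must be > 0")
    return _log_numerator(n, epsilon, mode) / r
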