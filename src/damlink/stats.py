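"""Self-contained study-design calculations.

Two-group sample size for a mean difference (normal approximation by
default, the noncentral-t iteration of statsmodels behind a flag), and the
qPCR relative-expression fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["PowerParams", "sample_size_two_group", "relative_expression"]


@dataclass
class PowerParams:
    """Design assumptions for a two-group comparison of means.

    ``fold_change`` is relative to a unit baseline, so the absolute
    difference is ``fold_change - 1`` against standard deviation ``sd``
    (e.g. a 1.5-fold change with sd 0.3 gives standardized effect
    d = 0.5 / 0.3).
    """

    power: float = 0.80
    alpha: float = 0.05  # two-sided
    fold_change: float = 1.5
    sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fold_change <= 0 or self.sd <= 0:
            raise ValueError("fold_change and sd must be positive")


def sample_size_two_group(
    params: PowerParams | None = None, method: str = "normal"
) -> int:
    """Smallest per-group n for a two-sided two-group comparison of means.

    ``method="normal"`` uses the closed form
    ``n = ceil(2 (z_{1-alpha/2} + z_{power})^2 / d^2)`` with
    ``d = (fold_change - 1) / sd`` and a floor of 2. ``method="t"`` iterates
    the noncentral-t power (statsmodels); it is stricter and can require one
    more animal per group.
    """
    params = params or PowerParams()
    d = (params.fold_change - 1.0) / params.sd
    if d == 0:
        raise ValueError("zero effect size: fold_change of exactly 1")
    d = abs(d)
    if method == "normal":
        z = norm.ppf(1 - params.alpha / 2) + norm.ppf(params.power)
        n = math.ceil(2 * z * z / (d * d))
    elif method == "t":
        from statsmodels.stats.power import TTestIndPower

        n = math.ceil(
            TTestIndPower().solve_power(
                effect_size=d, alpha=params.alpha, power=params.power,
                ratio=1.0, alternative="two-sided",
            )
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return max(int(n), 2)


def relative_expression(delta_delta_ct: float) -> float:
    """qPCR fold change ``2 ** ddCt`` for a signed ddCt.

    The sign convention is the caller's: orient ddCt so that a lower target
    Ct than control (earlier amplification, i.e. enrichment) gives a
    positive value and hence a fold change > 1. With the opposite
    orientation use the negated value (the textbook ``2^(-ddCt)`` form).
    """
    dd = float(delta_delta_ct)
    if not math.isfinite(dd):
        raise ValueError("delta_delta_ct must be finite")
    return 2.0 ** dd
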