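"""Reliable change index statistics and the significance decision.

Two z-type statistics are provided:

* CTT form:  RCI = (X_post - X_pre) / SEd, with SEd either the constant
  sqrt(2)*SEM form or the pooled sqrt(SE_pre^2 + SE_post^2) form.
* IRT form:  RCI = (theta_post - theta_pre) /
  sqrt(SE^2(theta_post) + SE^2(theta_pre)), with occasion-specific trait
  estimates and standard errors from any of the scoring methods.

Under the no-change null both statistics are referred to a standard normal;
``decide`` applies a two-sided test by default (one-sided directions are
available).  A statistic landing exactly on the critical value is retained.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.stats import norm

from .estimators import TraitEstimate


@dataclasses.dataclass(frozen=True)
class DecisionRule:
    """Significance level and sidedness for the reliable-change test."""

    level: float = 0.10
    sidedness: str = "two-sided"  # "two-sided" | "less" | "greater"

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.sidedness not in ("two-sided", "less", "greater"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclasses.dataclass(frozen=True)
class RCIResult:
    statistic: float
    p_value: float
    reject: bool
    direction: int  # sign of (post - pre)


def sed_pooled(se_pre: float, se_post: float) -> float:
    """Pooled standard error of a difference, sqrt(SE_pre^2 + SE_post^2)."""
    if se_pre <= 0 or se_post <= 0:
        raise ValueError("standard errors must be positive")
    return math.hypot(se_pre, se_post)


def rci_ctt(x_pre: float, x_post: float, sed: float) -> float:
    """CTT reliable change statistic (X_post - X_pre) / SEd."""
    if sed <= 0:
        raise ValueError(f"sed must be positive, got {sed}")
    return (x_post - x_pre) / sed


def rci_irt(pre: TraitEstimate, post: TraitEstimate) -> float:
    """IRT reliable change statistic on the latent scale."""
    return rci_ctt(pre.theta_hat, post.theta_hat, sed_pooled(pre.se, post.se))


def p_value(statistic: float, sidedness: str = "two-sided") -> float:
    if sidedness == "two-sided":
        return float(2.0 * norm.sf(abs(statistic)))
    if sidedness == "less":
        return float(norm.cdf(statistic))
    return float(norm.sf(statistic))


def decide(statistic: float, rule: DecisionRule = DecisionRule()) -> RCIResult:
    """Convert a statistic to a p-value and a reject/retain decision.

    Rejects when p < level strictly, so a statistic exactly at the critical
    value is retained.
    """
    p = p_value(statistic, rule.sidedness)
    return RCIResult(
        statistic=float(statistic),
        p_value=p,
        reject=bool(p < rule.level),
        direction=int(np.sign(statistic)),
    )


def reject_two_sided(statistics: np.ndarray, level: float = 0.10) -> np.ndarray:
    """Vectorized two-sided decision for simulation use."""
    crit = norm.ppf(1.0 - level / 2.0)
    return np.abs(np.asarray(statistics)) > crit
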