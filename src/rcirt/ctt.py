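"""Classical test theory scoring: sum scores, coefficient alpha, SEM, SEd.

The CTT reliable change index needs a constant standard error of the
difference score, SEd = sqrt(2) * SEM with SEM = SD(X) * sqrt(1 - alpha),
where alpha is the internal-consistency reliability of the calibration
sample and SD(X) the calibration-sample standard deviation of the sum
scores.  ``calibrate_ctt`` obtains these quantities by simulating a large
calibration sample from a stated latent population (the replicated design
uses a "clinical" population theta ~ N(1/2, 1)).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .estimators import GaussianPrior
from .grm import GRMItemBank, ResponseMatrix, simulate_responses


@dataclasses.dataclass(frozen=True)
class CTTCalibration:
    """Reliability and error quantities of a fixed test form.

    Satisfies ``sem = score_sd * sqrt(1 - reliability)`` and
    ``sed = sqrt(2) * sem`` (constant-SE convention).
    """

    reliability: float
    score_sd: float
    sem: float
    sed: float


def sum_score(pattern: Sequence[int]) -> int:
    """Unweighted sum of 0-based category codes."""
    pattern = np.asarray(pattern, dtype=int)
    if np.any(pattern < 0):
        raise ValueError("category codes must be nonnegative")
    return int(pattern.sum())


def sum_scores(resp: ResponseMatrix | np.ndarray) -> np.ndarray:
    values = resp.values if isinstance(resp, ResponseMatrix) else np.asarray(resp)
    return values.sum(axis=1)


def coefficient_alpha(resp: ResponseMatrix | np.ndarray) -> float:
    """Cronbach's coefficient alpha, (J/(J-1)) (1 - sum var_j / var_total).

    Uses N-1 sample variances.  Raises for fewer than two persons or items,
    or when the total-score variance is zero.
    """
    values = resp.values if isinstance(resp, ResponseMatrix) else np.asarray(resp, dtype=float)
    n, j = values.shape
    if n < 2:
        raise ValueError("coefficient alpha requires at least two persons")
    if j < 2:
        raise ValueError("coefficient alpha requires at least two items")
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = values.var(axis=0, ddof=1).sum()
    return float(j / (j - 1) * (1.0 - item_var / total_var))


def calibrate_ctt(
    bank: GRMItemBank,
    population: GaussianPrior,
    n_cal: int,
    rng: np.random.Generator,
) -> CTTCalibration:
    """Estimate reliability, SEM and SEd for one test form by simulation.

    Draws ``n_cal`` latent values from ``population``, simulates responses
    from ``bank``, and computes coefficient alpha and the sum-score SD.
    """
    if n_cal < 2:
        raise ValueError("n_cal must be at least 2")
    thetas = rng.normal(population.mean, population.sd, size=n_cal)
    resp = simulate_responses(bank, thetas, rng)
    alpha = coefficient_alpha(resp)
    sd = float(sum_scores(resp).std(ddof=1))
    sem = sd * math.sqrt(max(1.0 - alpha, 0.0))
    return CTTCalibration(alpha, sd, sem, math.sqrt(2.0) * sem)
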