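"""Monte Carlo study of reliable-change detection under the GRM.

Replicates the crossed design of the change-detection literature: test
lengths J in {5, 10, 20}; true latent changes delta_theta in
{0, -1/2, -1, -1.5} (negative values encode improvement on a severity
trait); a conditional theta grid from -2.5 to 3.5; two item-generation
designs (homogeneous and heterogeneous five-category items); and scoring
by WML or by EAP under post-test priors N(0,1), N(-0.2,1), N(-0.5,1),
N(-0.8,1), with the pre-test always scored under N(0,1).  The CTT arm uses
a constant SEd calibrated on a "clinical" population theta ~ N(1/2, 1).

Within each replication a fresh item bank is sampled; at each grid theta,
``N`` pre/post response-pattern pairs are simulated independently, scored,
and turned into reliable-change statistics.  Per-cell summaries are the
empirical rejection rate at the stated level and the bias and RMSD of the
estimated change delta_theta_hat = theta_hat_post - theta_hat_pre.

Two profiles are provided: the full design (grid step .05, R=100, N=5000)
and a desk profile (grid step 0.5, R=20, N=500) sized for interactive runs
and the packaged checks.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .ctt import CTTCalibration, calibrate_ctt, coefficient_alpha, sum_scores
from .estimators import GaussianPrior, batch_estimate
from .grm import GRMItem, GRMItemBank, simulate_responses
from .rci import reject_two_sided

logger = logging.getLogger("rcirt.simulation")

#: the four post-test EAP priors studied (Cohen's-d-sized mean shifts)
STUDY_PRIORS = (
    GaussianPrior(0.0, 1.0),
    GaussianPrior(-0.2, 1.0),
    GaussianPrior(-0.5, 1.0),
    GaussianPrior(-0.8, 1.0),
)

#: calibration population for the CTT arm ("clinical" population)
CLINICAL_POPULATION = GaussianPrior(0.5, 1.0)


@dataclasses.dataclass(frozen=True)
class ItemDesign:
    """Item-generation scheme for five-category graded items.

    Slopes are uniform on ``slope_range``; each item's thresholds are the
    ``base_thresholds`` plus a per-item uniform shift from ``shift_range``
    (a common shift preserves the ascending order).
    """

    label: str
    slope_range: tuple[float, float]
    base_thresholds: tuple[float, ...]
    shift_range: tuple[float, float]

    @classmethod
    def homogeneous(cls) -> "ItemDesign":
        """Narrow-range symptom items: slopes U[1.5,2.5], thresholds
        (-1,-0.5,0.5,1) + b̄ with b̄ ~ U[0,1.25]."""
        return cls("homogeneous", (1.5, 2.5), (-1.0, -0.5, 0.5, 1.0), (0.0, 1.25))

    @classmethod
    def heterogeneous(cls) -> "ItemDesign":
        """Wide-range items: slopes U[1,2.5], thresholds
        (-0.5,-0.2,0.2,0.5) + b̄ with b̄ ~ U[-1.5,2.5]."""
        return cls("heterogeneous", (1.0, 2.5), (-0.5, -0.2, 0.2, 0.5), (-1.5, 2.5))

    @classmethod
    def from_label(cls, label: str) -> "ItemDesign":
        try:
            return {"homogeneous": cls.homogeneous, "heterogeneous": cls.heterogeneous}[label]()
        except KeyError:
            raise ValueError(f"unknown item design {label!r}") from None


def sample_item_bank(design: ItemDesign, J: int, rng: np.random.Generator) -> GRMItemBank:
    """Draw a fresh bank of ``J`` items from an item-generation design."""
    slopes = rng.uniform(*design.slope_range, size=J)
    shifts = rng.uniform(*design.shift_range, size=J)
    base = np.asarray(design.base_thresholds, dtype=float)
    return GRMItemBank(
        GRMItem(float(a), base + s) for a, s in zip(slopes, shifts)
    )


@dataclasses.dataclass(frozen=True)
class EstimatorSpec:
    """A scoring rule for the study: method plus post-test prior.

    ``method`` is one of ``"wml"``, ``"ml"``, ``"map"``, ``"eap"``,
    ``"ctt"``.  For Bayesian methods the pre-test is always scored under
    N(0,1); ``prior`` is the post-test prior.
    """

    method: str
    prior: GaussianPrior | None = None

    def __post_init__(self) -> None:
        m = self.method.lower()
        object.__setattr__(self, "method", m)
        if m in ("eap", "map") and self.prior is None:
            raise ValueError(f"{m.upper()} estimator requires a post-test prior")

    @property
    def label(self) -> str:
        if self.method in ("eap", "map"):
            mu = self.prior.mean
            var = self.prior.var
            return f"{self.method.upper()} N({mu:g},{var:g})"
        return self.method.upper()


def study_estimators(include_ctt: bool = False) -> list[EstimatorSpec]:
    """WML plus the four studied EAP priors (optionally the CTT arm)."""
    specs = [EstimatorSpec("wml")]
    specs += [EstimatorSpec("eap", p) for p in STUDY_PRIORS]
    if include_ctt:
        specs.append(EstimatorSpec("ctt"))
    return specs


@dataclasses.dataclass(frozen=True)
class ConditionSpec:
    """One fully specified simulation condition."""

    J: int
    delta_theta: float
    design: ItemDesign
    estimators: tuple[EstimatorSpec, ...]
    theta_grid: tuple[float, ...]
    R: int = 20
    N: int = 500
    level: float = 0.10
    seed: int = 0
    n_cal: int = 20000  # CTT calibration sample per replication bank

    def __post_init__(self) -> None:
        if self.delta_theta > 0:
            raise ValueError(
                "delta_theta must be <= 0 (negative shifts encode improvement)"
            )
        grid = tuple(float(t) for t in self.theta_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("theta_grid must be strictly ascending")
        object.__setattr__(self, "theta_grid", grid)
        object.__setattr__(self, "estimators", tuple(self.estimators))

    @classmethod
    def desk(cls, J, delta_theta, design, estimators=None, seed=0, **kw) -> "ConditionSpec":
        """Desk profile: grid step 0.5, R=20, N=500."""
        grid = tuple(np.round(np.arange(-2.5, 3.5 + 1e-9, 0.5), 10))
        ests = tuple(estimators) if estimators is not None else tuple(study_estimators())
        return cls(J, delta_theta, design, ests, grid, **{"R": 20, "N": 500, "seed": seed, **kw})

    @classmethod
    def paper(cls, J, delta_theta, design, estimators=None, seed=0, **kw) -> "ConditionSpec":
        """Full profile: grid step .05, R=100, N=5000 (long-running)."""
        grid = tuple(np.round(np.arange(-2.5, 3.5 + 1e-9, 0.05), 10))
        ests = tuple(estimators) if estimators is not None else tuple(study_estimators())
        return cls(J, delta_theta, design, ests, grid,
                   **{"R": 100, "N": 5000, "n_cal": 100000, "seed": seed, **kw})


@dataclasses.dataclass(frozen=True)
class CellResult:
    """Per-(theta, estimator) outcome summary of one simulated cell."""

    theta: float
    rejection_rate: float
    mean_delta_hat: float
    bias: float
    rmsd: float
    n_eff: int


def _score_occasion(bank, values, spec: EstimatorSpec, occasion: str):
    """Score one occasion's responses under an estimator spec.

    Bayesian methods use the N(0,1) prior for the pre-test and the spec's
    prior for the post-test.
    """
    if spec.method in ("eap", "map"):
        prior = GaussianPrior(0.0, 1.0) if occasion == "pre" else spec.prior
        return batch_estimate(bank, values, spec.method, prior)
    return batch_estimate(bank, values, spec.method)


def _evaluate_cell(
    bank: GRMItemBank,
    pre_values: np.ndarray,
    post_values: np.ndarray,
    theta: float,
    delta_theta: float,
    estimators: Sequence[EstimatorSpec],
    level: float,
    ctt_cal: CTTCalibration | None,
) -> list[CellResult]:
    """Score one simulated cell with every estimator, sharing scorings."""
    n = pre_values.shape[0]
    cache: dict[tuple, tuple] = {}

    def scored(values, spec, occasion):
        if spec.method in ("eap", "map"):
            prior = GaussianPrior(0.0, 1.0) if occasion == "pre" else spec.prior
            key = (occasion, spec.method, prior.mean, prior.var)
        else:
            key = (occasion, spec.method)
        if key not in cache:
            cache[key] = _score_occasion(bank, values, spec, occasion)
        return cache[key]

    out = []
    for spec in estimators:
        if spec.method == "ctt":
            if ctt_cal is None:
                raise ValueError("CTT estimator requires a calibration")
            z = (sum_scores(post_values) - sum_scores(pre_values)) / ctt_cal.sed
            rate = float(reject_two_sided(z, level).mean())
            out.append(CellResult(theta, rate, math.nan, math.nan, math.nan, n))
            continue
        th_pre, se_pre, _ = scored(pre_values, spec, "pre")
        th_post, se_post, _ = scored(post_values, spec, "post")
        z = (th_post - th_pre) / np.sqrt(se_pre**2 + se_post**2)
        rate = float(reject_two_sided(z, level).mean())
        delta_hat = th_post - th_pre
        err = delta_hat - delta_theta
        out.append(
            CellResult(
                theta=theta,
                rejection_rate=rate,
                mean_delta_hat=float(delta_hat.mean()),
                bias=float(err.mean()),
                rmsd=float(np.sqrt(np.mean(err**2))),
                n_eff=n,
            )
        )
    return out


def run_cell(
    bank: GRMItemBank,
    theta: float,
    delta_theta: float,
    estimator: EstimatorSpec,
    n: int,
    level: float,
    rng: np.random.Generator,
    ctt_cal: CTTCalibration | None = None,
) -> CellResult:
    """Simulate and evaluate a single (bank, theta, estimator) cell.

    Draws ``n`` pre-test patterns at ``theta`` and ``n`` post-test patterns
    at ``theta + delta_theta`` and summarizes the resulting reliable-change
    decisions and change-score errors.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    pre = simulate_responses(bank, np.full(n, theta), rng)
    post = simulate_responses(bank, np.full(n, theta + delta_theta), rng)
    return _evaluate_cell(
        bank, pre.values, post.values, theta, delta_theta, [estimator], level, ctt_cal
    )[0]


def run_condition(spec: ConditionSpec) -> pd.DataFrame:
    """Run one condition over its theta grid and replications.

    Each replication samples a fresh item bank from the design and, at every
    grid theta, simulates ``spec.N`` independent pre/post pattern pairs that
    are shared across estimators.  Returns a tidy frame with one row per
    (replication, theta, estimator).  Fully reproducible from ``spec.seed``
    via deterministically spawned child seeds.
    """
    root = np.random.SeedSequence(spec.seed)
    rep_seqs = root.spawn(spec.R)
    needs_ctt = any(e.method == "ctt" for e in spec.estimators)
    rows = []
    for r, rep_seq in enumerate(rep_seqs):
        cell_seqs = rep_seq.spawn(len(spec.theta_grid) + 2)
        bank = sample_item_bank(spec.design, spec.J, np.random.default_rng(cell_seqs[0]))
        ctt_cal = None
        if needs_ctt:
            ctt_cal = calibrate_ctt(
                bank, CLINICAL_POPULATION, spec.n_cal, np.random.default_rng(cell_seqs[1])
            )
        for t_idx, theta in enumerate(spec.theta_grid):
            rng = np.random.default_rng(cell_seqs[t_idx + 2])
            pre = simulate_responses(bank, np.full(spec.N, theta), rng)
            post = simulate_responses(bank, np.full(spec.N, theta + spec.delta_theta), rng)
            cells = _evaluate_cell(
                bank, pre.values, post.values, theta, spec.delta_theta,
                spec.estimators, spec.level, ctt_cal,
            )
            for est, cell in zip(spec.estimators, cells):
                rows.append(
                    {
                        "design": spec.design.label,
                        "J": spec.J,
                        "delta_theta": spec.delta_theta,
                        "estimator": est.label,
                        "replication": r,
                        "theta": theta,
                        "n": cell.n_eff,
                        "rejection_rate": cell.rejection_rate,
                        "mean_delta_hat": cell.mean_delta_hat,
                        "bias": cell.bias,
                        "rmsd": cell.rmsd,
                    }
                )
        logger.info("condition J=%d dtheta=%g: replication %d/%d done",
                    spec.J, spec.delta_theta, r + 1, spec.R)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation


_KEYS = ["design", "J", "delta_theta", "estimator"]


def conditional_rates(results: pd.DataFrame) -> pd.DataFrame:
    """Rejection rate per grid theta, averaged over replications, with a
    Monte Carlo standard error from between-replication variation."""
    g = results.groupby(_KEYS + ["theta"], sort=True)
    out = g.agg(
        rate=("rejection_rate", "mean"),
        mc_se=("rejection_rate", lambda x: x.std(ddof=1) / math.sqrt(len(x))),
        n_reps=("rejection_rate", "size"),
    ).reset_index()
    return out


def marginal_recovery(results: pd.DataFrame) -> pd.DataFrame:
    """Marginal bias and RMSD per condition, averaged over the theta grid
    and replications (RMSD pooled through the mean squared deviation)."""
    df = results.dropna(subset=["bias"])
    g = df.groupby(_KEYS, sort=True)
    out = g.apply(
        lambda x: pd.Series(
            {
                "bias": x["bias"].mean(),
                "rmsd": math.sqrt((x["rmsd"] ** 2).mean()),
            }
        ),
        include_groups=False,
    ).reset_index()
    return out


def typeI_power_report(results: pd.DataFrame) -> pd.DataFrame:
    """Long-format rejection-rate table labelled Type I (delta_theta = 0)
    or power (delta_theta < 0)."""
    rates = conditional_rates(results)
    rates["metric"] = np.where(rates["delta_theta"] == 0, "type_I", "power")
    return rates


def plot_rates(report: pd.DataFrame, path: str) -> None:
    """Optional rejection-rate plot (one panel per J, lines per estimator)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    js = sorted(report["J"].unique())
    fig, axes = plt.subplots(1, len(js), figsize=(4 * len(js), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, j in zip(axes, js):
        sub = report[report["J"] == j]
        for est, grp in sub.groupby("estimator"):
            ax.plot(grp["theta"], grp["rate"], label=est)
        ax.axhline(0.10, ls="--", c="k", lw=0.8)
        ax.set_title(f"J = {j}")
        ax.set_xlabel(r"$\theta$")
    axes[0].set_ylabel("rejection rate")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# population reliability of the sampled test forms


def population_reliability(
    design: ItemDesign,
    J: int,
    rng: np.random.Generator,
    n_banks: int = 50,
    n_cal: int = 100_000,
    population: GaussianPrior = CLINICAL_POPULATION,
) -> dict:
    """Average CTT calibration over freshly sampled item banks.

    Mirrors how the study's population reliability values are obtained:
    sample ``n_banks`` banks from the design, simulate ``n_cal`` calibration
    respondents from the (clinical) population for each, and average
    coefficient alpha and the derived error quantities.
    """
    alphas, sds, sems, seds = [], [], [], []
    for _ in range(n_banks):
        bank = sample_item_bank(design, J, rng)
        cal = calibrate_ctt(bank, population, n_cal, rng)
        alphas.append(cal.reliability)
        sds.append(cal.score_sd)
        sems.append(cal.sem)
        seds.append(cal.sed)
    return {
        "design": design.label,
        "J": J,
        "n_banks": n_banks,
        "n_cal": n_cal,
        "reliability": float(np.mean(alphas)),
        "reliability_se": float(np.std(alphas, ddof=1) / math.sqrt(n_banks)),
        "score_sd": float(np.mean(sds)),
        "sem": float(np.mean(sems)),
        "sed": float(np.mean(seds)),
    }
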