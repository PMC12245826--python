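"""Graded response model (GRM) primitives.

The GRM models an ordered polytomous item response X_j in {0, ..., K_j - 1}
through cumulative logistic curves

    P*_jk(theta) = Pr(X_j >= k | theta) = 1 / (1 + exp(-a_j (theta - b_jk)))

for k = 1..K_j-1, with a common item slope a_j > 0 and strictly ascending
thresholds b_j1 < ... < b_j,K-1.  Category probabilities are adjacent
differences of the cumulative curves.  The logistic metric is used without
the historical 1.7 scaling constant, matching the parameterization of modern
IRT software (e.g. mirt); slopes calibrated under a 1.7-scaled normal-ogive
approximation must be rescaled before use.

This module provides probabilities, log-likelihoods, expected Fisher
information, and response simulation, both per pattern and vectorized over
persons and latent-trait grids.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

#: floor applied to category probabilities before taking logarithms so that
#: likelihoods stay finite for any response pattern
PROB_FLOOR = 1e-10

#: default latent-trait search interval for point estimators
THETA_BOUNDS = (-6.0, 6.0)


@dataclasses.dataclass(frozen=True)
class GRMItem:
    """A single graded-response item: slope ``a`` and ascending thresholds."""

    a: float
    b: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "b", b)
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"item slope must be positive, got {self.a}")
        if b.ndim != 1 or b.size < 1:
            raise ValueError("thresholds must be a non-empty 1-d sequence")
        if not np.all(np.diff(b) > 0):
            raise ValueError(f"thresholds must be strictly ascending, got {b}")

    @property
    def n_cat(self) -> int:
        return self.b.size + 1


class GRMItemBank:
    """An ordered collection of graded-response items.

    Parameters
    ----------
    items
        Iterable of ``GRMItem`` or ``(a, thresholds)`` pairs.  Items may have
        different numbers of categories.
    """

    def __init__(self, items: Iterable) -> None:
        parsed = []
        for it in items:
            if isinstance(it, GRMItem):
                parsed.append(it)
            else:
                a, b = it
                parsed.append(GRMItem(float(a), np.asarray(b, dtype=float)))
        self.items: list[GRMItem] = parsed

    @property
    def J(self) -> int:
        return len(self.items)

    @property
    def n_cat(self) -> np.ndarray:
        """Category count per item."""
        return np.array([it.n_cat for it in self.items], dtype=int)

    @property
    def max_score(self) -> int:
        """Largest attainable unweighted sum score, sum_j (K_j - 1)."""
        return int(sum(it.n_cat - 1 for it in self.items))

    def __len__(self) -> int:
        return self.J

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, j: int) -> GRMItem:
        return self.items[j]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GRMItemBank) or self.J != other.J:
            return NotImplemented if not isinstance(other, GRMItemBank) else False
        return all(
            a.a == b.a and a.b.shape == b.b.shape and np.array_equal(a.b, b.b)
            for a, b in zip(self.items, other.items)
        )

    def __repr__(self) -> str:
        return f"GRMItemBank(J={self.J}, n_cat={list(self.n_cat)})"

    def validate_pattern(self, pattern: Sequence[int]) -> np.ndarray:
        pattern = np.asarray(pattern, dtype=int)
        if pattern.ndim != 1 or pattern.size != self.J:
            raise ValueError(
                f"pattern length {pattern.size} does not match bank size {self.J}"
            )
        ncat = self.n_cat
        if np.any(pattern < 0) or np.any(pattern >= ncat):
            bad = np.where((pattern < 0) | (pattern >= ncat))[0][0]
            raise ValueError(
                f"category {pattern[bad]} out of range for item {bad} "
                f"(K={ncat[bad]})"
            )
        return pattern


@dataclasses.dataclass(frozen=True)
class ResponseMatrix:
    """N x J integer response table with 0-based category codes."""

    values: np.ndarray
    person_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=int)
        if values.ndim != 2:
            raise ValueError("response matrix must be 2-dimensional")
        object.__setattr__(self, "values", values)
        if self.person_ids is not None:
            ids = np.asarray(self.person_ids)
            if ids.size != values.shape[0]:
                raise ValueError("person_ids length does not match row count")
            object.__setattr__(self, "person_ids", ids)

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    def validate_against(self, bank: GRMItemBank) -> None:
        if self.J != bank.J:
            raise ValueError(
                f"response matrix has {self.J} items but bank has {bank.J}"
            )
        ncat = bank.n_cat
        bad = (self.values < 0) | (self.values >= ncat[None, :])
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"response {self.values[i, j]} at row {i}, item {j} outside "
                f"0..{ncat[j] - 1}"
            )


@dataclasses.dataclass(frozen=True)
class QuadratureGrid:
    """Latent-trait quadrature: ascending nodes with normalized weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("quadrature grid needs at least two nodes")
        if not np.all(np.diff(nodes) > 0):
            raise ValueError("quadrature nodes must be strictly ascending")
        if np.any(weights < 0):
            raise ValueError("quadrature weights must be nonnegative")
        total = weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("quadrature weights must have positive sum")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / total)

    @property
    def n(self) -> int:
        return self.nodes.size

    @classmethod
    def for_density(
        cls, mean: float, sd: float, n_nodes: int = 101, span: float = 6.0
    ) -> "QuadratureGrid":
        """Equally spaced nodes on mean +/- span*sd, weighted by the
        Gaussian density and renormalized."""
        nodes = np.linspace(mean - span * sd, mean + span * sd, n_nodes)
        z = (nodes - mean) / sd
        weights = np.exp(-0.5 * z**2)
        return cls(nodes, weights)


# ---------------------------------------------------------------------------
# probabilities


def cumulative_prob(item: GRMItem, k: int, theta) -> np.ndarray | float:
    """P*_k(theta) = Pr(X >= k | theta) for boundary index k in 1..K-1."""
    if not 1 <= k <= item.n_cat - 1:
        raise IndexError(f"boundary index {k} outside 1..{item.n_cat - 1}")
    return expit(item.a * (np.asarray(theta, dtype=float) - item.b[k - 1]))


def category_prob(item: GRMItem, theta) -> np.ndarray:
    """Category probability vector P_k(theta), k = 0..K-1.

    For array ``theta`` of shape ``(G,)`` returns shape ``(K, G)``.  Entries
    are exact adjacent differences of the cumulative curves and sum to one;
    the probability floor is applied only where logarithms are taken.
    """
    theta = np.asarray(theta, dtype=float)
    pstar = expit(item.a * (theta[..., None] - item.b))  # (..., K-1)
    ones = np.ones_like(theta[..., None][..., :1])
    zeros = np.zeros_like(ones)
    full = np.concatenate([ones, pstar, zeros], axis=-1)  # (..., K+1)
    probs = -np.diff(full, axis=-1)  # (..., K)
    return np.moveaxis(probs, -1, 0) if theta.ndim else probs


def log_category_prob(item: GRMItem, theta) -> np.ndarray:
    """log P_k(theta) with the probability floor applied."""
    return np.log(np.maximum(category_prob(item, theta), PROB_FLOOR))


def log_likelihood(bank: GRMItemBank, pattern: Sequence[int], theta) -> np.ndarray | float:
    """Response-pattern log-likelihood sum_j log P_{j, x_j}(theta).

    ``theta`` may be scalar or an array; the result has ``theta``'s shape.
    """
    pattern = bank.validate_pattern(pattern)
    theta = np.asarray(theta, dtype=float)
    out = np.zeros_like(theta)
    for j, item in enumerate(bank):
        out = out + log_category_prob(item, theta)[pattern[j]]
    return out if theta.ndim else float(out)


# ---------------------------------------------------------------------------
# information


def item_information(item: GRMItem, theta) -> np.ndarray | float:
    """Expected Fisher information of one graded item.

    I_j(theta) = sum_k (P'_k)^2 / P_k with
    P'_k = a [P*_k(1-P*_k) - P*_{k+1}(1-P*_{k+1})], P*_0 = 1, P*_K = 0.
    """
    theta = np.asarray(theta, dtype=float)
    pstar = expit(item.a * (theta[..., None] - item.b))
    ones = np.ones_like(theta[..., None][..., :1])
    zeros = np.zeros_like(ones)
    full = np.concatenate([ones, pstar, zeros], axis=-1)  # (..., K+1)
    w = full * (1.0 - full)
    dprob = item.a * (w[..., :-1] - w[..., 1:])  # P'_k, (..., K)
    probs = -np.diff(full, axis=-1)
    info = np.sum(dprob**2 / np.maximum(probs, PROB_FLOOR), axis=-1)
    return info if theta.ndim else float(info)


def test_information(bank: GRMItemBank, theta) -> np.ndarray | float:
    """Test information: sum of item informations."""
    theta = np.asarray(theta, dtype=float)
    out = np.zeros_like(theta)
    for item in bank:
        out = out + item_information(item, theta)
    return out if theta.ndim else float(out)


# ---------------------------------------------------------------------------
# simulation


def simulate_responses(
    bank: GRMItemBank, thetas: Sequence[float], rng: np.random.Generator
) -> ResponseMatrix:
    """Draw one response pattern per latent value in ``thetas``.

    Uses the inverse-survival construction: with U ~ U(0,1), the response
    ``sum_k 1[U < P*_k(theta)]`` has exactly the GRM category distribution,
    because Pr(X >= k) = P*_k and the cumulative curves are ordered.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 1:
        raise ValueError("thetas must be a 1-d array")
    n = thetas.size
    values = np.empty((n, bank.J), dtype=np.int64)
    for j, item in enumerate(bank):
        pstar = expit(item.a * (thetas[:, None] - item.b))  # (n, K-1)
        u = rng.random(n)
        values[:, j] = np.sum(u[:, None] < pstar, axis=1)
    return ResponseMatrix(values)


# ---------------------------------------------------------------------------
# vectorized log-likelihood tables (shared by the batch estimators)


def log_prob_tables(bank: GRMItemBank, nodes: np.ndarray) -> list[np.ndarray]:
    """Per-item log category-probability tables on a node grid.

    Returns a list of ``(K_j, G)`` arrays, floored before the log.
    """
    nodes = np.asarray(nodes, dtype=float)
    return [log_category_prob(item, nodes) for item in bank]


def loglik_matrix(
    bank: GRMItemBank, responses: np.ndarray, nodes: np.ndarray
) -> np.ndarray:
    """Log-likelihood of each response row at each node: shape (N, G)."""
    responses = np.asarray(responses, dtype=int)
    if responses.ndim == 1:
        responses = responses[None, :]
    tables = log_prob_tables(bank, nodes)
    out = np.zeros((responses.shape[0], len(nodes)))
    for j, tab in enumerate(tables):
        out += tab[responses[:, j], :]
    return out
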