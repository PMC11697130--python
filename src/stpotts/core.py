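"""Probability components of the nonparametric Potts cell-typing model.

The model places a Potts prior over cell-type labels ``C`` on a directed
k-nearest-neighbour graph,

    P(C | beta, {pi_l}) ∝ prod_i pi_{C_i} * exp(beta * sum_i sum_{j in Nei(i)} 1[C_i = C_j]),

where the external-field weights ``pi`` come from a stick-breaking process
(``pi_1 = xi_1``, ``pi_l = xi_l * prod_{m<l} (1 - xi_m)`` with
``xi_l ~ Beta(1, alpha)``), so the number of cell types is unbounded a priori.
Observed per-cell features (principal components of expression) are modelled
as diagonal Gaussians ``Y_hi | C_i = l ~ N(eta_hl, sigma_h^2)``.

Labels are 1-based positive integers throughout the public interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import NeighborGraph, directed_agreement_count

__all__ = [
    "SticksState",
    "PottsParams",
    "EmissionParams",
    "Hyperparams",
    "stick_weights",
    "extend_sticks",
    "potts_log_score",
    "emission_loglik_cell",
    "exact_potts_distribution",
]

# Stick variables live strictly inside (0, 1); draws that hit a boundary in
# floating point are clamped this far inside so every pi_l stays positive.
_XI_EPS = 1e-12


class SticksState:
    """Finite instantiated prefix of the stick-breaking weights.

    Parameters
    ----------
    xi : array-like of float in (0, 1)
        Instantiated stick variables ``xi_1, ..., xi_L``.
    alpha : float
        Concentration parameter of the Beta(1, alpha) stick prior. Larger
        values favour more occupied clusters absent spatial interaction.
    """

    def __init__(self, xi, alpha: float = 1.0):
        xi = np.atleast_1d(np.asarray(xi, dtype=float))
        if xi.ndim != 1:
            raise ValueError("xi must be one-dimensional")
        if np.any(xi <= 0.0) or np.any(xi >= 1.0):
            raise ValueError("stick variables must lie strictly in (0, 1)")
        if not alpha > 0:
            raise ValueError("alpha must be positive")
        self.xi = xi
        self.alpha = float(alpha)

    def __len__(self) -> int:
        return self.xi.size

    def copy(self) -> "SticksState":
        return SticksState(self.xi.copy(), self.alpha)

    def weights(self, L: int | None = None) -> np.ndarray:
        """Weights ``pi_1..pi_L`` (all instantiated sticks by default)."""
        if L is None:
            L = len(self)
        return stick_weights(self, L)

    def tail_mass(self, L: int | None = None) -> float:
        """Mass prod_{m<=L} (1 - xi_m) left beyond the first ``L`` sticks."""
        if L is None:
            L = len(self)
        if L > len(self):
            raise ValueError(f"only {len(self)} sticks instantiated, asked for {L}")
        return float(np.prod(1.0 - self.xi[:L]))

    def append(self, xi_new) -> None:
        xi_new = np.clip(np.atleast_1d(np.asarray(xi_new, float)),
                         _XI_EPS, 1.0 - _XI_EPS)
        self.xi = np.concatenate([self.xi, xi_new])


def stick_weights(sticks: SticksState, L: int) -> np.ndarray:
    """First ``L`` stick-breaking weights pi_l = xi_l * prod_{m<l}(1 - xi_m)."""
    if L < 1:
        raise ValueError("L must be a positive integer")
    if L > len(sticks):
        raise ValueError(
            f"{L} weights requested but only {len(sticks)} sticks instantiated; "
            "call extend_sticks first"
        )
    xi = sticks.xi[:L]
    # cumulative leftover before each stick: 1, (1-xi_1), (1-xi_1)(1-xi_2), ...
    leftover = np.concatenate([[1.0], np.cumprod(1.0 - xi[:-1])])
    return xi * leftover


def extend_sticks(sticks: SticksState, u_min: float, rng: np.random.Generator) -> SticksState:
    """Extend sticks with Beta(1, alpha) prior draws until the tail mass
    drops below ``u_min``.

    After extension no un-instantiated label can have ``pi_l >= u_min``, so
    slice-truncated candidate sets built from the instantiated prefix are
    complete. Mutates and returns ``sticks``.
    """
    if not (0.0 < u_min < 1.0):
        raise ValueError("u_min must lie in (0, 1)")
    tail = sticks.tail_mass()
    while tail >= u_min:
        xi_new = float(np.clip(rng.beta(1.0, sticks.alpha), _XI_EPS, 1.0 - _XI_EPS))
        sticks.append(xi_new)
        tail *= 1.0 - sticks.xi[-1]
    return sticks


@dataclass
class PottsParams:
    """Interaction strength and external-field sticks of the Potts prior."""

    beta: float
    sticks: SticksState

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")


@dataclass
class EmissionParams:
    """Gaussian emission parameters: eta is H x L, sigma2 length H (shared
    across clusters)."""

    eta: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.eta.ndim != 2:
            raise ValueError("eta must be an H x L matrix")
        if np.any(self.sigma2 <= 0):
            raise ValueError("all sigma_h^2 must be positive")
        if not np.all(np.isfinite(self.eta)):
            raise ValueError("eta must be finite")


@dataclass
class Hyperparams:
    """Prior and proposal hyperparameters.

    a_beta, tau2_beta : location/scale of the truncated-normal prior on beta.
    a_eta, b2_eta     : mean/variance of the normal prior on cluster means.
    kappa, tau        : shape/scale of the inverse-gamma prior on sigma_h^2.
    alpha             : stick-breaking concentration.
    R0                : proposal truncation depth — sticks 1..R0 get random-walk
                        proposals, deeper sticks are refreshed from the prior.
    tau2_0, tau2_1    : proposal variances for the xi and beta random walks.
    """

    a_beta: float = 1.0
    tau2_beta: float = 1.0
    a_eta: float = 0.0
    b2_eta: float = 10.0
    kappa: float = 2.0
    tau: float = 1.0
    alpha: float = 1.0
    R0: int = 50
    tau2_0: float = 0.01
    tau2_1: float = 0.01

    def __post_init__(self):
        for name in ("tau2_beta", "b2_eta", "kappa", "tau", "alpha", "tau2_0", "tau2_1"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.R0 < 1:
            raise ValueError("R0 must be a positive integer")


def potts_log_score(C, graph: NeighborGraph, params: PottsParams) -> float:
    """Unnormalized log-probability of labels ``C`` under the Potts prior.

    sum_i log pi_{C_i} + beta * (number of agreeing directed neighbour pairs).
    """
    C = np.asarray(C, dtype=np.int64)
    L = int(C.max())
    if L > len(params.sticks):
        raise ValueError(
            f"label {L} exceeds the {len(params.sticks)} instantiated sticks"
        )
    pi = params.sticks.weights()
    agree = directed_agreement_count(C, graph)
    return float(np.sum(np.log(pi[C - 1])) + params.beta * agree)


def emission_loglik_cell(y_i, label: int, em: EmissionParams) -> float:
    """Gaussian emission log-likelihood sum_h log N(Y_hi | eta_h,label, sigma_h^2)."""
    y_i = np.asarray(y_i, dtype=float)
    if not 1 <= label <= em.eta.shape[1]:
        raise ValueError(f"label {label} has no instantiated emission mean")
    resid = y_i - em.eta[:, label - 1]
    return float(
        -0.5 * np.sum(resid * resid / em.sigma2)
        - 0.5 * np.sum(np.log(2.0 * np.pi * em.sigma2))
    )


def emission_loglik_matrix(Y: np.ndarray, em: EmissionParams) -> np.ndarray:
    """n x L matrix of per-cell, per-cluster emission log-likelihoods.

    ``Y`` is the H x n matrix of principal-component scores.
    """
    # (n, H, L) broadcast; small for desk-scale H and instantiated L.
    diff = Y.T[:, :, None] - em.eta[None, :, :]
    quad = np.sum(diff * diff / em.sigma2[None, :, None], axis=1)
    const = 0.5 * np.sum(np.log(2.0 * np.pi * em.sigma2))
    return -0.5 * quad - const


def enumerate_label_vectors(n: int, L: int) -> np.ndarray:
    """All L^n label vectors over {1..L}, shape (L^n, n), lexicographic."""
    grids = np.meshgrid(*([np.arange(1, L + 1)] * n), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def exact_potts_distribution(graph: NeighborGraph, beta: float, pi, L: int):
    """Exhaustive normalized distribution of the Potts model truncated to
    ``L`` labels (testing oracle for tiny instances).

    ``pi`` is renormalized over the L labels. Returns ``(configs, probs)``
    where ``configs`` has shape (L^n, n) with 1-based labels and ``probs``
    sums to one.
    """
    n = graph.n
    if L ** n > 10 ** 6:
        raise ValueError(f"instance too large to enumerate: L^n = {L}^{n}")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    pi = np.asarray(pi, dtype=float)[:L]
    pi = pi / pi.sum()
    configs = enumerate_label_vectors(n, L)
    log_pi_sum = np.sum(np.log(pi[configs - 1]), axis=1)
    agree = np.zeros(configs.shape[0], dtype=np.int64)
    for i in range(n):
        for j in graph.neighbors[i]:
            agree += configs[:, i] == configs[:, j]
    logw = log_pi_sum + beta * agree
    logw -= logw.max()
    w = np.exp(logw)
    return configs, w / w.sum()
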