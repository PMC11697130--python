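"""Partially collapsed Gibbs sampler for the nonparametric Potts model.

One iteration performs, in order:

(a) a joint double Metropolis--Hastings update of the interaction strength
    beta and the stick variables xi: propose by random walk (sticks beyond
    depth R0 refreshed from the prior), simulate auxiliary labels C* by one
    sequential Gibbs sweep under the proposal, and accept with the exchange
    ratio — the intractable Potts normalizing constant cancels;
(b) slice variables u_i ~ Unif(0, pi_{C_i}), truncating the infinite label
    space to the finite candidate sets {l : pi_l >= u_i};
(c) a sequential sweep over cells redrawing each label from
    P(C_i = l) ∝ exp(beta * #agreeing neighbours) * N(Y_i | eta_l, sigma^2)
    over the candidate set;
(d) conjugate normal updates of the cluster means eta;
(e) conjugate inverse-gamma updates of the per-component variances sigma^2.

All randomness flows through one ``numpy.random.Generator``, so chains are
bit-reproducible given the seed. Products are accumulated in log space and
per-cell conditionals normalized by max-subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._truncnorm import truncnorm_logpdf, truncnorm_rvs
from .core import (
    EmissionParams,
    Hyperparams,
    PottsParams,
    SticksState,
    emission_loglik_matrix,
    extend_sticks,
)
from .graph import NeighborGraph, directed_agreement_count

__all__ = [
    "ModelState",
    "MCMCConfig",
    "ChainOutput",
    "initialize_state",
    "sample_u",
    "update_labels",
    "update_eta",
    "update_sigma2",
    "propose_beta_xi",
    "auxiliary_gibbs_sweep",
    "double_mh_accept",
    "merge_split_move",
    "run_mcmc",
    "summarize_labels",
]


@dataclass
class ModelState:
    """Current sampler state; labels are 1-based, eta columns align with sticks."""

    C: np.ndarray            # (n,) int64 labels
    u: np.ndarray            # (n,) slice variables, u_i in (0, pi_{C_i}]
    beta: float
    sticks: SticksState
    eta: np.ndarray          # (H, L) cluster means, L = len(sticks)
    sigma2: np.ndarray       # (H,)

    @property
    def potts(self) -> PottsParams:
        return PottsParams(self.beta, self.sticks)

    @property
    def em(self) -> EmissionParams:
        return EmissionParams(self.eta, self.sigma2)

    def occupied(self) -> int:
        return int(np.unique(self.C).size)


@dataclass
class MCMCConfig:
    n_iter: int = 6000
    burn_in: int = 3000
    seed: int = 0
    init_K: int = 8
    thin: int = 1
    store_full_C: bool = True
    # interior Gibbs sweeps when simulating the auxiliary labels C* in the
    # exchange update; one sweep leaves C* too correlated with C and biases
    # the beta posterior upward (checked against an exact-constant chain)
    n_aux_sweeps: int = 3
    # Metropolis-Hastings merge-split move on the labels once per iteration;
    # single-site sweeps cannot merge duplicated clusters once the spatial
    # field orders, so this move carries the cluster-number mixing
    merge_split: bool = True
    # fraction of burn-in over which the spatial interaction in the label
    # sweep is ramped from 0 to its sampled value; at the study coupling the
    # Potts conditionals are supercritical and a cold start freezes the
    # k-means partition, so labels first organize by expression alone.
    # Retained samples are always produced by the exact kernel (0 disables).
    anneal_frac: float = 1.0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.init_K < 1 or self.thin < 1 or self.n_aux_sweeps < 1:
            raise ValueError("init_K, thin and n_aux_sweeps must be positive")
        if not 0.0 <= self.anneal_frac <= 1.0:
            raise ValueError("anneal_frac must lie in [0, 1]")


@dataclass
class ChainOutput:
    """Post-burn-in retained samples and acceptance diagnostics."""

    C_samples: np.ndarray      # (S, n) or shape (0, n) when not stored
    beta_samples: np.ndarray   # (S,)
    K_trace: np.ndarray        # (S,) occupied-cluster counts
    accept_rate: float
    n_iter: int
    burn_in: int
    thin: int
    n_validated: int = 0   # stored iterations that passed the invariant checks

    @property
    def n_stored(self) -> int:
        return self.beta_samples.size


def _sync_eta(state: ModelState, hyper: Hyperparams, rng: np.random.Generator) -> None:
    """Append prior-drawn mean columns until eta covers every stick."""
    L = len(state.sticks)
    H, have = state.eta.shape
    if have < L:
        fresh = rng.normal(hyper.a_eta, np.sqrt(hyper.b2_eta), size=(H, L - have))
        state.eta = np.concatenate([state.eta, fresh], axis=1)


def initialize_state(Y, graph: NeighborGraph, hyper: Hyperparams, cfg: MCMCConfig,
                     rng: np.random.Generator) -> ModelState:
    """Seeded k-means initialization of labels, moments and sticks.

    Cluster means start at the k-means sample means, variances at the pooled
    within-cluster variances (floored at 1e-6), beta at its prior location,
    and the sticks are inverted so the instantiated weights match the
    empirical cluster frequencies (with a 1% tail reserved for new clusters).
    """
    from sklearn.cluster import KMeans

    Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
    H, n = Y.shape
    if cfg.init_K > n:
        raise ValueError(f"init_K={cfg.init_K} exceeds the number of cells {n}")
    km_seed = int(rng.integers(2 ** 31 - 1))
    km = KMeans(n_clusters=cfg.init_K, n_init=10, random_state=km_seed)
    C = km.fit_predict(Y.T).astype(np.int64) + 1

    K = cfg.init_K
    eta = np.empty((H, K))
    for lab in range(1, K + 1):
        members = C == lab
        eta[:, lab - 1] = Y[:, members].mean(axis=1) if members.any() else \
            rng.normal(hyper.a_eta, np.sqrt(hyper.b2_eta), size=H)
    resid = Y - eta[:, C - 1]
    sigma2 = np.maximum(np.mean(resid * resid, axis=1), 1e-6)

    # Invert the stick construction so pi matches empirical frequencies
    # shrunk by 1%, leaving positive tail mass for future clusters.
    freq = np.bincount(C, minlength=K + 1)[1:] / n
    target = np.maximum(freq, 1e-6) * 0.99
    target *= 0.99 / target.sum()
    xi = np.empty(K)
    remaining = 1.0
    for lab in range(K):
        xi[lab] = np.clip(target[lab] / remaining, 1e-6, 1.0 - 1e-6)
        remaining *= 1.0 - xi[lab]
    sticks = SticksState(xi, alpha=hyper.alpha)
    while len(sticks) < hyper.R0:
        sticks.append(rng.beta(1.0, hyper.alpha))

    state = ModelState(C=C, u=np.empty(n), beta=float(hyper.a_beta),
                       sticks=sticks, eta=eta, sigma2=sigma2)
    _sync_eta(state, hyper, rng)
    sample_u(state, rng)
    return state


def sample_u(state: ModelState, rng: np.random.Generator) -> np.ndarray:
    """Step (b): u_i ~ Unif(0, pi_{C_i}) independently."""
    pi = state.sticks.weights()
    state.u = rng.uniform(0.0, pi[state.C - 1])
    # uniform() can return exactly 0; the slice variable must be positive
    state.u = np.maximum(state.u, 1e-300)
    return state.u


def ensure_candidates(state: ModelState, hyper: Hyperparams,
                      rng: np.random.Generator) -> None:
    """Extend sticks (and emission means) until the tail is below min_i u_i,
    so every candidate set {l : pi_l >= u_i} is fully instantiated."""
    extend_sticks(state.sticks, float(state.u.min()), rng)
    _sync_eta(state, hyper, rng)


def update_labels(state: ModelState, Y, graph: NeighborGraph,
                  rng: np.random.Generator, beta_scale: float = 1.0) -> np.ndarray:
    """Step (c): sequential label sweep over the slice-truncated candidate sets.

    The conditional exponent counts agreements over every edge touching cell
    i (out- and in-neighbours, with multiplicity), matching the full
    conditional of the directed Potts joint. Within the sweep, neighbour
    labels reflect cells already updated earlier in the scan (fixed index
    order).
    """
    Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
    pi = state.sticks.weights()
    L = pi.size
    if state.sticks.tail_mass() >= state.u.min():
        raise RuntimeError("sticks not extended below min u; call ensure_candidates first")
    E = emission_loglik_matrix(Y, state.em)   # (n, L); eta/sigma2 fixed in (c)
    C = state.C
    beta = state.beta * beta_scale
    indptr, indices = graph.conditional_adjacency()
    u = state.u
    n = C.size
    v = rng.uniform(size=n)
    for i in range(n):
        cand = np.flatnonzero(pi >= u[i])     # 0-based candidate labels
        if cand.size == 0:
            raise RuntimeError(f"empty candidate set for cell {i}")
        if cand.size == 1:
            C[i] = cand[0] + 1
            continue
        counts = np.bincount(C[indices[indptr[i]:indptr[i + 1]]], minlength=L + 1)
        logp = beta * counts[cand + 1] + E[i, cand]
        logp -= logp.max()
        w = np.exp(logp)
        cum = np.cumsum(w)
        C[i] = cand[np.searchsorted(cum, v[i] * cum[-1], side="right").clip(0, cand.size - 1)] + 1
    return C


def update_eta(state: ModelState, Y, hyper: Hyperparams,
               rng: np.random.Generator) -> np.ndarray:
    """Step (d): conjugate normal draw for every instantiated cluster mean.

    Posterior mean (sum_i Y_hi / sigma_h^2 + a_eta / b_eta^2) / (m_l / sigma_h^2
    + 1 / b_eta^2); empty clusters fall back to the N(a_eta, b_eta^2) prior.
    """
    Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
    H, n = Y.shape
    L = len(state.sticks)
    onehot = np.zeros((n, L))
    onehot[np.arange(n), state.C - 1] = 1.0
    m = onehot.sum(axis=0)                       # (L,)
    sums = Y @ onehot                            # (H, L)
    prec = m[None, :] / state.sigma2[:, None] + 1.0 / hyper.b2_eta
    mean = (sums / state.sigma2[:, None] + hyper.a_eta / hyper.b2_eta) / prec
    state.eta = rng.normal(mean, np.sqrt(1.0 / prec))
    return state.eta


def update_sigma2(state: ModelState, Y, hyper: Hyperparams,
                  rng: np.random.Generator) -> np.ndarray:
    """Step (e): sigma_h^2 ~ inv-Gamma(kappa + n/2, tau + RSS_h / 2)."""
    Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
    n = Y.shape[1]
    resid = Y - state.eta[:, state.C - 1]
    shape = hyper.kappa + 0.5 * n
    scale = hyper.tau + 0.5 * np.sum(resid * resid, axis=1)
    state.sigma2 = scale / rng.gamma(shape, 1.0, size=scale.shape)
    return state.sigma2


def propose_beta_xi(state: ModelState, hyper: Hyperparams,
                    rng: np.random.Generator) -> tuple[SticksState, float]:
    """Substep (a1): random-walk proposals for (xi, beta).

    Sticks 1..R0 move by a truncated-normal walk on (0, 1); sticks beyond R0
    are refreshed from the Beta(1, alpha) prior; beta moves by a truncated-
    normal walk on (0, inf).
    """
    xi = state.sticks.xi
    L = xi.size
    R0 = min(hyper.R0, L)
    xi_star = np.empty(L)
    xi_star[:R0] = truncnorm_rvs(xi[:R0], hyper.tau2_0, 0.0, 1.0, rng)
    if L > R0:
        xi_star[R0:] = rng.beta(1.0, hyper.alpha, size=L - R0)
    xi_star = np.clip(xi_star, 1e-12, 1.0 - 1e-12)
    beta_star = float(truncnorm_rvs(state.beta, hyper.tau2_1, 0.0, np.inf, rng, size=()))
    return SticksState(xi_star, alpha=hyper.alpha), beta_star


def auxiliary_gibbs_sweep(C_init, sticks_star: SticksState, beta_star: float,
                          graph: NeighborGraph, rng: np.random.Generator,
                          max_label: int = 100_000) -> np.ndarray:
    """Substep (a2): one sequential sweep generating the auxiliary labels C*.

    Starting from the current labels, each C*_i is redrawn by inverse CDF
    from p*_il ∝ pi*_l * exp(beta* a_il) for l <= R_i and pi*_l beyond, where
    R_i is the largest label among i's touching neighbours and a_il the
    number of edges touching i (out and in, with multiplicity) whose other
    endpoint carries label l — the full conditional of the directed Potts
    joint under the proposed parameters. Draws falling in the un-instantiated
    tail extend the proposal sticks with Beta(1, alpha) prior draws.
    """
    C = np.asarray(C_init, dtype=np.int64).copy()
    indptr, indices = graph.conditional_adjacency()
    pi = sticks_star.weights()
    tail = sticks_star.tail_mass()
    n = C.size
    for i in range(n):
        nb = C[indices[indptr[i]:indptr[i + 1]]]
        R_i = int(nb.max())
        while R_i > pi.size:   # defensive; labels should be instantiated
            sticks_star.append(rng.beta(1.0, sticks_star.alpha))
            pi = np.append(pi, sticks_star.xi[-1] * tail)
            tail *= 1.0 - sticks_star.xi[-1]
        counts = np.bincount(nb, minlength=R_i + 1)[1:R_i + 1]
        head = pi[:R_i] * np.exp(beta_star * counts)
        D = 1.0 - pi[:R_i].sum() + head.sum()
        cum = np.cumsum(head) / D
        v = rng.uniform()
        if R_i > 0 and v <= cum[-1]:
            C[i] = int(np.searchsorted(cum, v, side="left")) + 1
            continue
        acc = cum[-1] if R_i > 0 else 0.0
        lab = R_i
        while True:
            lab += 1
            if lab > pi.size:
                sticks_star.append(rng.beta(1.0, sticks_star.alpha))
                pi = np.append(pi, sticks_star.xi[-1] * tail)
                tail *= 1.0 - sticks_star.xi[-1]
            acc += pi[lab - 1] / D
            if v <= acc:
                break
            if lab >= max_label:
                raise RuntimeError("auxiliary sweep failed to terminate")
        C[i] = lab
    return C


def double_mh_accept(current, proposal, graph: NeighborGraph, hyper: Hyperparams,
                     rng: np.random.Generator) -> tuple[bool, float]:
    """Substep (a3): exchange-ratio accept/reject for (xi, beta).

    ``current`` is (sticks, beta, C) and ``proposal`` is
    (sticks_star, beta_star, C_star). The log ratio is the product of the
    prior ratio over sticks 1..R0 and beta, the reversed proposal ratio, and
    the exchange factor

        [prod_i pi*_{C_i} e^{beta* S(C)}] [prod_i pi_{C*_i} e^{beta S(C*)}]
        -----------------------------------------------------------------
        [prod_i pi_{C_i}  e^{beta  S(C)}] [prod_i pi*_{C*_i} e^{beta* S(C*)}]

    with S the directed agreement count — each configuration re-scored under
    the swapped parameters, cancelling the normalizing constants.
    """
    sticks, beta, C = current
    sticks_s, beta_s, C_s = proposal
    xi, xi_s = sticks.xi, sticks_s.xi
    R0 = min(hyper.R0, xi.size, xi_s.size)

    log_prior = (hyper.alpha - 1.0) * (
        np.sum(np.log1p(-xi_s[:R0])) - np.sum(np.log1p(-xi[:R0]))
    )
    log_prior += float(
        truncnorm_logpdf(beta_s, hyper.a_beta, hyper.tau2_beta, 0.0, np.inf)
        - truncnorm_logpdf(beta, hyper.a_beta, hyper.tau2_beta, 0.0, np.inf)
    )

    log_prop = float(
        np.sum(truncnorm_logpdf(xi[:R0], xi_s[:R0], hyper.tau2_0, 0.0, 1.0))
        - np.sum(truncnorm_logpdf(xi_s[:R0], xi[:R0], hyper.tau2_0, 0.0, 1.0))
    )
    log_prop += float(
        truncnorm_logpdf(beta, beta_s, hyper.tau2_1, 0.0, np.inf)
        - truncnorm_logpdf(beta_s, beta, hyper.tau2_1, 0.0, np.inf)
    )

    pi = sticks.weights()
    pi_s = sticks_s.weights()
    S_C = directed_agreement_count(C, graph)
    S_Cs = directed_agreement_count(C_s, graph)
    lp = np.log(pi)
    lp_s = np.log(pi_s)
    log_exch = (
        lp_s[C - 1].sum() + beta_s * S_C + lp[C_s - 1].sum() + beta * S_Cs
        - (lp[C - 1].sum() + beta * S_C + lp_s[C_s - 1].sum() + beta_s * S_Cs)
    )

    log_r = log_prior + log_prop + log_exch
    if not np.isfinite(log_r):
        warnings.warn("non-finite double-MH log ratio; proposal rejected", stacklevel=2)
        rng.uniform()  # keep the stream aligned with the accept draw
        return False, float(log_r)
    accept = np.log(rng.uniform()) < min(0.0, log_r)
    return bool(accept), float(log_r)


def _pair_cross_agreements(members_a, members_b, graph: NeighborGraph) -> int:
    """Directed agreements gained by merging label sets A and B: each
    directed edge with one endpoint in A and the other in B is counted once
    via the touching lists of the B-side cells."""
    indptr, indices = graph.conditional_adjacency()
    in_a = np.zeros(graph.n, dtype=bool)
    in_a[members_a] = True
    total = 0
    for i in members_b:
        total += int(in_a[indices[indptr[i]:indptr[i + 1]]].sum())
    return total


def _restricted_allocation(cells, side, log_pi_a, log_pi_b, em_a, em_b, beta,
                           graph: NeighborGraph, rng):
    """Sequential two-way allocation of ``cells`` (increasing index order).

    If ``side`` is None the allocation is sampled; otherwise its density is
    evaluated at the given assignment (True = side b). Each cell's side
    probability is proportional to pi_side * exp(beta * #already-allocated
    touching neighbours on that side) * emission(side); cells outside the
    pair carry neither label, so they contribute nothing. Returns
    ``(side, log_density)``.
    """
    indptr, indices = graph.conditional_adjacency()
    assigned = np.zeros(graph.n, dtype=np.int8)   # 0 unallocated, 1 = a, 2 = b
    sampled = side is None
    if sampled:
        side = np.zeros(len(cells), dtype=bool)
    logq = 0.0
    for t, i in enumerate(cells):
        nb = assigned[indices[indptr[i]:indptr[i + 1]]]
        la = log_pi_a + beta * int((nb == 1).sum()) + em_a[t]
        lb = log_pi_b + beta * int((nb == 2).sum()) + em_b[t]
        m = max(la, lb)
        pb = np.exp(lb - m) / (np.exp(la - m) + np.exp(lb - m))
        if sampled:
            side[t] = rng.uniform() < pb
        logq += np.log(pb) if side[t] else np.log1p(-pb)
        assigned[i] = 2 if side[t] else 1
    return side, logq


def merge_split_move(state: ModelState, Y, graph: NeighborGraph,
                     hyper: Hyperparams, rng: np.random.Generator) -> bool:
    """Metropolis--Hastings merge-split move on the labels.

    With probability 1/2 proposes merging one occupied cluster into another,
    with probability 1/2 splitting an occupied cluster onto an empty
    instantiated stick, using a restricted sequential allocation (emissions +
    spatial coupling) as the proposal; the acceptance ratio is exact because
    the Potts normalizing constant does not depend on C. Single-site sweeps
    cannot traverse the low-probability configurations separating a
    duplicated cluster from its merged counterpart once the spatial coupling
    orders the field; this move jumps between those modes directly.
    """
    Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
    C = state.C
    occ = np.unique(C)
    K = occ.size
    L = len(state.sticks)
    pi = state.sticks.weights()
    log_pi = np.log(pi)
    beta = state.beta
    do_merge = rng.uniform() < 0.5

    if do_merge:
        if K < 2:
            return False
        a, b = rng.choice(occ, size=2, replace=False)
        members_a = np.flatnonzero(C == a)
        members_b = np.flatnonzero(C == b)
        cells = np.sort(np.concatenate([members_a, members_b]))
        em = emission_loglik_matrix(Y[:, cells], state.em)
        em_a = em[:, a - 1]
        em_b = em[:, b - 1]
        side = np.isin(cells, members_b)
        _, logq_alloc = _restricted_allocation(cells, side, log_pi[a - 1],
                                               log_pi[b - 1], em_a, em_b,
                                               beta, graph, rng)
        dS = _pair_cross_agreements(members_a, members_b, graph)
        dlogP = (members_b.size * (log_pi[a - 1] - log_pi[b - 1])
                 + float((em_a - em_b)[side].sum()) + beta * dS)
        # reverse: split chosen among K-1 occupied and L-(K-1) empty sticks
        log_q_rev = -np.log(K - 1) - np.log(L - (K - 1)) + logq_alloc
        log_q_fwd = -np.log(K) - np.log(K - 1)
        if np.log(rng.uniform()) < min(0.0, dlogP + log_q_rev - log_q_fwd):
            C[members_b] = a
            return True
        return False

    # split
    if L - K < 1:
        return False
    a = int(rng.choice(occ))
    empties = np.setdiff1d(np.arange(1, L + 1), occ)
    b = int(rng.choice(empties))
    cells = np.flatnonzero(C == a)
    if cells.size < 2:
        return False
    em = emission_loglik_matrix(Y[:, cells], state.em)
    em_a = em[:, a - 1]
    em_b = em[:, b - 1]
    side, logq_alloc = _restricted_allocation(cells, None, log_pi[a - 1],
                                              log_pi[b - 1], em_a, em_b,
                                              beta, graph, rng)
    if side.all() or not side.any():
        return False                      # degenerate split: nothing moved
    members_b = cells[side]
    members_a = cells[~side]
    dS = _pair_cross_agreements(members_a, members_b, graph)
    dlogP = (members_b.size * (log_pi[b - 1] - log_pi[a - 1])
             + float((em_b - em_a)[side].sum()) - beta * dS)
    log_q_fwd = -np.log(K) - np.log(L - K) + logq_alloc
    log_q_rev = -np.log(K + 1) - np.log(K)   # reverse merge choice (b into a)
    if np.log(rng.uniform()) < min(0.0, dlogP + log_q_rev - log_q_fwd):
        C[members_b] = b
        return True
    return False


def _step_a(state: ModelState, graph: NeighborGraph, hyper: Hyperparams,
            rng: np.random.Generator, n_aux_sweeps: int = 1) -> bool:
    """Full double-MH update (a1)-(a3); mutates state on acceptance."""
    sticks_star, beta_star = propose_beta_xi(state, hyper, rng)
    C_star = state.C
    for _ in range(n_aux_sweeps):
        C_star = auxiliary_gibbs_sweep(C_star, sticks_star, beta_star, graph, rng)
    # The sweep may have instantiated deeper sticks under the proposal; match
    # the current set with prior draws so pi_{C*} is defined on both sides.
    while len(state.sticks) < len(sticks_star):
        state.sticks.append(rng.beta(1.0, hyper.alpha))
    _sync_eta(state, hyper, rng)
    accept, _ = double_mh_accept(
        (state.sticks, state.beta, state.C),
        (sticks_star, beta_star, C_star),
        graph, hyper, rng,
    )
    if accept:
        state.sticks = sticks_star
        state.beta = beta_star
    return accept


def _check_invariants(state: ModelState) -> None:
    pi = state.sticks.weights()
    if np.any(state.u > pi[state.C - 1]):
        raise AssertionError("slice invariant u_i <= pi_{C_i} violated")
    mass = pi.sum() + state.sticks.tail_mass()
    if abs(mass - 1.0) > 1e-12:
        raise AssertionError(f"stick mass conservation violated: {mass}")
    if state.sticks.tail_mass() >= state.u.min():
        raise AssertionError("candidate sets not finite: tail mass >= min u")
    if state.eta.shape[1] != len(state.sticks):
        raise AssertionError("emission means out of sync with sticks")


def run_mcmc(Y, graph: NeighborGraph, hyper: Hyperparams, cfg: MCMCConfig,
             *, validate: bool = False, verbose: int = 0,
             callback=None) -> ChainOutput:
    """Run the full partially collapsed Gibbs sampler.

    Executes steps (a)-(e) per iteration, stores post-burn-in samples every
    ``cfg.thin`` iterations, and is bit-reproducible given ``cfg.seed``.
    With ``validate=True`` the slice/stick invariants are asserted at every
    stored iteration.
    """
    Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
    if Y.shape[1] != graph.n:
        raise ValueError("PC matrix and graph disagree on the number of cells")
    rng = np.random.default_rng(cfg.seed)
    state = initialize_state(Y, graph, hyper, cfg, rng)

    C_store, beta_store, K_store = [], [], []
    n_accept = 0
    n_validated = 0
    n_ramp = int(cfg.anneal_frac * cfg.burn_in)
    for it in range(1, cfg.n_iter + 1):
        n_accept += _step_a(state, graph, hyper, rng,
                            n_aux_sweeps=cfg.n_aux_sweeps)  # (a)
        if cfg.merge_split:
            merge_split_move(state, Y, graph, hyper, rng)  # C-marginal move
        sample_u(state, rng)                               # (b)
        ensure_candidates(state, hyper, rng)               # (c) truncation
        beta_scale = min(1.0, it / n_ramp) if n_ramp > 0 else 1.0
        update_labels(state, Y, graph, rng, beta_scale=beta_scale)  # (c) sweep
        update_eta(state, Y, hyper, rng)                   # (d)
        update_sigma2(state, Y, hyper, rng)                # (e)

        if it > cfg.burn_in and (it - cfg.burn_in - 1) % cfg.thin == 0:
            if validate:
                _check_invariants(state)
                n_validated += 1
            if cfg.store_full_C:
                C_store.append(state.C.copy())
            beta_store.append(state.beta)
            K_store.append(state.occupied())
        if verbose and it % verbose == 0:
            print(f"iter {it:>6d}  beta={state.beta:.3f}  K={state.occupied()}  "
                  f"accept={n_accept / it:.3f}")
        if callback is not None:
            callback(it, state)

    C_samples = np.asarray(C_store, dtype=np.int64) if C_store else \
        np.empty((0, graph.n), dtype=np.int64)
    return ChainOutput(
        C_samples=C_samples,
        beta_samples=np.asarray(beta_store),
        K_trace=np.asarray(K_store, dtype=np.int64),
        accept_rate=n_accept / cfg.n_iter,
        n_iter=cfg.n_iter,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
        n_validated=n_validated,
    )


def _greedy_match(ref, labels):
    """Relabel ``labels`` onto ``ref``'s alphabet by greedy maximum overlap."""
    ref_vals = np.unique(ref)
    lab_vals = np.unique(labels)
    overlap = {(a, b): int(np.sum((ref == a) & (labels == b)))
               for a in ref_vals for b in lab_vals}
    pairs = sorted(overlap, key=lambda ab: (-overlap[ab], ab[0], ab[1]))
    used_a, mapping = set(), {}
    for a, b in pairs:
        if a not in used_a and b not in mapping and overlap[(a, b)] > 0:
            mapping[b] = a
            used_a.add(a)
    nxt = int(ref_vals.max()) + 1
    for b in lab_vals:
        if b not in mapping:
            mapping[b] = nxt
            nxt += 1
    out = labels.copy()
    for b, a in mapping.items():
        out[labels == b] = a
    return out


def summarize_labels(chain: ChainOutput) -> tuple[np.ndarray, int]:
    """Point-estimate labels: greedy-overlap alignment to the first stored
    sample, then the per-cell mode (ties to the lowest label).

    Returns ``(point_labels, K_hat)`` with K_hat the number of distinct
    labels in the point estimate.
    """
    if chain.C_samples.shape[0] == 0:
        raise ValueError("chain holds no stored label samples")
    ref = chain.C_samples[0]
    aligned = np.stack([ref] + [_greedy_match(ref, s) for s in chain.C_samples[1:]])
    n = ref.size
    point = np.empty(n, dtype=np.int64)
    for i in range(n):
        point[i] = np.bincount(aligned[:, i]).argmax()
    return point, int(np.unique(point).size)
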