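"""Synthetic single-cell spatial transcriptomics data with known truth.

Generates scattered 2-D coordinates, spatially coherent ground-truth labels
from a finite-K Potts model (Gibbs sweeps on the k-NN graph), and Gaussian
low-dimensional features around well-separated cluster means — optionally
lifted to overdispersed negative-binomial gene counts to exercise the
normalize/log/PCA preprocessing path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .graph import build_knn_graph, directed_agreement_count
from .io import CellCoordinates, ExpressionMatrix, PCMatrix

__all__ = ["SimConfig", "simulate_positions", "simulate_potts_labels",
           "simulate_expression", "simulate_dataset"]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    mean_separation is the scale of the cluster-mean arrangement in units of
    the emission standard deviation: means sit at
    ``mean_separation * sigma_gen`` times distinct signed binary codes, so
    any two cluster means are at least ``2 * mean_separation * sigma_gen``
    apart in Euclidean distance.
    """

    n_cells: int = 500
    layout: str = "uniform-scatter"       # or "jittered-grid"
    K_true: int = 4
    beta_gen: float = 1.0
    pi_gen: np.ndarray | None = None      # defaults to uniform over K_true
    k_sim: int = 6
    H_sim: int = 3
    mean_separation: float = 5.0
    sigma2_gen: float = 1.0
    seed: int = 0
    emit_counts: bool = False
    nb_dispersion: float = 2.0
    n_sweeps: int = 50
    grid_jitter: float = 0.1   # sd of grid jitter, in grid-step units

    def __post_init__(self):
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.pi_gen is None:
            self.pi_gen = np.full(self.K_true, 1.0 / self.K_true)
        self.pi_gen = np.asarray(self.pi_gen, dtype=float)
        if self.pi_gen.size != self.K_true or not np.isclose(self.pi_gen.sum(), 1.0):
            raise ValueError("pi_gen must be a length-K_true probability vector")
        if self.mean_separation < 0 or self.sigma2_gen <= 0 or self.beta_gen < 0:
            raise ValueError("invalid separation / variance / interaction values")
        if self.layout not in {"uniform-scatter", "jittered-grid"}:
            raise ValueError(f"unknown layout {self.layout!r}")


def simulate_positions(cfg: SimConfig, rng: np.random.Generator) -> CellCoordinates:
    """Cell coordinates on the unit square: i.i.d. uniform scatter, or a
    sqrt(n) grid with Gaussian jitter (sd = 0.1 grid step)."""
    n = cfg.n_cells
    if n < 2:
        raise ValueError("need at least two cells")
    if cfg.layout == "uniform-scatter":
        xy = rng.uniform(size=(n, 2))
    else:
        side = int(np.ceil(np.sqrt(n)))
        step = 1.0 / max(side - 1, 1)
        gx, gy = np.meshgrid(np.arange(side) * step, np.arange(side) * step,
                             indexing="ij")
        xy = np.column_stack([gx.ravel(), gy.ravel()])[:n]
        if cfg.grid_jitter > 0:
            xy = xy + rng.normal(0.0, cfg.grid_jitter * step, size=xy.shape)
    ids = [f"cell{i}" for i in range(n)]
    return CellCoordinates(xy, ids)


def simulate_potts_labels(coords: CellCoordinates, cfg: SimConfig,
                          rng: np.random.Generator,
                          n_sweeps: int | None = None):
    """Ground-truth labels from the K_true-label Potts model.

    Labels start i.i.d. from pi_gen and are refined by sequential Gibbs
    sweeps with conditional P(C_i = l) ∝ pi_l * exp(beta_gen * #neighbours
    with label l) on the k_sim-NN graph. Returns ``(labels, info)`` where
    info carries the realized directed agreement fraction.
    """
    if n_sweeps is None:
        n_sweeps = cfg.n_sweeps
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    n = coords.n
    labels = rng.choice(np.arange(1, cfg.K_true + 1), size=n, p=cfg.pi_gen)
    if cfg.K_true == 1:
        return labels, {"agreement_fraction": 1.0, "n_sweeps": 0}
    graph = build_knn_graph(coords, cfg.k_sim)
    log_pi = np.log(cfg.pi_gen)
    if cfg.beta_gen > 0:
        indptr, indices = graph.conditional_adjacency()
        for _ in range(n_sweeps):
            vs = rng.uniform(size=n)
            for i in range(n):
                counts = np.bincount(labels[indices[indptr[i]:indptr[i + 1]]],
                                     minlength=cfg.K_true + 1)[1:]
                logp = log_pi + cfg.beta_gen * counts
                logp -= logp.max()
                w = np.cumsum(np.exp(logp))
                labels[i] = int(np.searchsorted(w, vs[i] * w[-1], side="right")) + 1
    frac = directed_agreement_count(labels, graph) / (n * cfg.k_sim)
    return labels, {"agreement_fraction": float(frac), "n_sweeps": n_sweeps}


def _cluster_means(cfg: SimConfig) -> np.ndarray:
    """H_sim x K_true means at mean_separation * sigma_gen times distinct
    signed binary codes."""
    if cfg.K_true > 2 ** cfg.H_sim:
        raise ValueError(
            f"cannot place {cfg.K_true} distinct signed binary codes in "
            f"{cfg.H_sim} dimensions"
        )
    codes = np.array(list(itertools.product((1.0, -1.0), repeat=cfg.H_sim)))
    # Order codes by parity first so early codes differ in >= 2 coordinates.
    parity = np.argsort((codes < 0).sum(axis=1) % 2, kind="stable")
    codes = codes[parity][: cfg.K_true]
    return (cfg.mean_separation * np.sqrt(cfg.sigma2_gen)) * codes.T


def simulate_expression(labels, cfg: SimConfig, rng: np.random.Generator,
                        return_counts: bool | None = None):
    """Per-cell features Y_hi ~ N(eta_h,label, sigma2_gen) around the signed
    binary-code means; optionally lifted to negative-binomial counts over
    G = 5 * H_sim synthetic genes through a log-linear link.

    Returns a PCMatrix, or ``(PCMatrix, ExpressionMatrix)`` when counts are
    emitted.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 1 or labels.max() > cfg.K_true:
        raise ValueError("labels must lie in 1..K_true")
    if return_counts is None:
        return_counts = cfg.emit_counts
    means = _cluster_means(cfg)                       # (H, K)
    Y = means[:, labels - 1] + rng.normal(
        0.0, np.sqrt(cfg.sigma2_gen), size=(cfg.H_sim, labels.size))
    pcs = PCMatrix(Y)
    if not return_counts:
        return pcs
    G = 5 * cfg.H_sim
    B = rng.normal(0.0, 1.0, size=(G, cfg.H_sim))
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    # keep the linear predictor of order one so counts stay in a
    # realistic range (~exp(1.5 +- 1) per gene)
    lin = B @ (Y / max(np.abs(means).max(), 1.0))
    mu = np.exp(1.5 + lin)
    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).T   # cells x genes
    expr = ExpressionMatrix(
        counts,
        [f"cell{i}" for i in range(labels.size)],
        [f"gene{g}" for g in range(G)],
        is_count=True,
    )
    return pcs, expr


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: positions + Potts labels + expression.

    Returns ``(coords, labels, pcs)`` or ``(coords, labels, pcs, counts)``
    when ``cfg.emit_counts``; fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    coords = simulate_positions(cfg, rng)
    labels, _ = simulate_potts_labels(coords, cfg, rng)
    out = simulate_expression(labels, cfg, rng)
    if cfg.emit_counts:
        pcs, counts = out
        return coords, labels, pcs, counts
    return coords, labels, out
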