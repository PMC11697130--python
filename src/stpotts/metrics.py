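"""Clustering evaluation and chain diagnostics.

The adjusted Rand index is the headline evaluation metric, so it is
implemented here directly from the contingency-table pair-counting formula
(and cross-checked in the tests against both a brute-force pair enumeration
and scikit-learn's implementation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PartitionPair", "adjusted_rand_index", "chain_diagnostics"]


@dataclass
class PartitionPair:
    """Two equal-length label vectors over arbitrary label alphabets."""

    labels_a: np.ndarray
    labels_b: np.ndarray

    def __post_init__(self):
        self.labels_a = np.asarray(self.labels_a)
        self.labels_b = np.asarray(self.labels_b)
        if self.labels_a.shape != self.labels_b.shape or self.labels_a.ndim != 1:
            raise ValueError("partitions must be equal-length vectors")
        if self.labels_a.size < 2:
            raise ValueError("need at least two items")


def adjusted_rand_index(labels_a, labels_b=None) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    With contingency counts n_ij, row sums a_i, column sums b_j and
    T_xy = sum C(x, 2):

        ARI = (T_n - T_a T_b / C(n,2)) / ((T_a + T_b)/2 - T_a T_b / C(n,2))

    Returns 1 for identical partitions up to relabelling, ~0 at chance. When
    the denominator vanishes (both partitions trivial) the partitions are
    identical and 1 is returned.
    """
    if labels_b is None:
        pair = labels_a
    else:
        pair = PartitionPair(np.asarray(labels_a), np.asarray(labels_b))
    _, ia = np.unique(pair.labels_a, return_inverse=True)
    _, ib = np.unique(pair.labels_b, return_inverse=True)
    n = ia.size
    R, S = ia.max() + 1, ib.max() + 1
    table = np.zeros((R, S), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    t_n = comb2(table).sum()
    t_a = comb2(table.sum(axis=1)).sum()
    t_b = comb2(table.sum(axis=0)).sum()
    expected = t_a * t_b / comb2(n)
    denom = 0.5 * (t_a + t_b) - expected
    if denom == 0.0:
        return 1.0
    return float((t_n - expected) / denom)


def chain_diagnostics(chain) -> dict:
    """Summary report for a ChainOutput: beta trace moments and central 95%
    interval, occupied-cluster histogram, double-MH acceptance rate, and a
    split-half stability ARI between point estimates from the two halves."""
    from .sampler import ChainOutput, summarize_labels  # local: avoid cycle

    if chain.n_stored == 0:
        raise ValueError("chain holds no stored samples")
    beta = chain.beta_samples
    lo, hi = np.percentile(beta, [2.5, 97.5])
    ks, counts = np.unique(chain.K_trace, return_counts=True)
    report = {
        "beta_mean": float(beta.mean()),
        "beta_ci95": (float(lo), float(hi)),
        "K_histogram": dict(zip(ks.tolist(), counts.tolist())),
        "K_mode": int(ks[counts.argmax()]),
        "accept_rate": round(float(chain.accept_rate), 3),
        "n_stored": int(chain.n_stored),
    }
    S = chain.C_samples.shape[0]
    if S >= 2:
        half = S // 2
        first = ChainOutput(chain.C_samples[:half], beta[:half],
                            chain.K_trace[:half], chain.accept_rate,
                            chain.n_iter, chain.burn_in, chain.thin)
        second = ChainOutput(chain.C_samples[half:], beta[half:],
                             chain.K_trace[half:], chain.accept_rate,
                             chain.n_iter, chain.burn_in, chain.thin)
        la, _ = summarize_labels(first)
        lb, _ = summarize_labels(second)
        report["split_half_ari"] = adjusted_rand_index(la, lb)
    return report
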