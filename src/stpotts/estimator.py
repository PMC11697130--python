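"""scikit-learn-style estimators wrapping the preprocessing and the sampler.

``ExpressionPCA`` is a transformer implementing the normalize -> log ->
center -> PCA pipeline; ``PottsCellTyper`` is a clusterer running the full
MCMC and exposing point labels, the detected number of cell types, and the
chain. Both follow the sklearn conventions (get_params/set_params, fitted
attributes with trailing underscores), so they compose with pipelines and
model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .core import Hyperparams
from .graph import build_knn_graph
from .io import ExpressionMatrix, normalize_counts
from .metrics import chain_diagnostics
from .sampler import MCMCConfig, run_mcmc, summarize_labels

__all__ = ["ExpressionPCA", "PottsCellTyper"]


class ExpressionPCA(TransformerMixin, BaseEstimator):
    """Library-size normalization, log(1+x), gene centering and PCA.

    Parameters
    ----------
    n_components : int, default 50
        Number of principal components to retain.
    normalize : bool, default True
        Scale each cell's counts to the median total count of the fit data.
    log1p : bool, default True
        Apply log(1 + x) after normalization.
    scale_genes : bool, default False
        Standardize genes to unit variance before PCA.

    Attributes
    ----------
    components_ : (n_components, n_genes) loadings, sign-fixed so each
        component's largest-absolute loading is positive.
    explained_variance_ : per-component variance, non-increasing.
    mean_ : per-gene mean of the processed fit data.
    library_target_ : the normalization target (median total count).
    """

    def __init__(self, n_components: int = 50, *, normalize: bool = True,
                 log1p: bool = True, scale_genes: bool = False):
        self.n_components = n_components
        self.normalize = normalize
        self.log1p = log1p
        self.scale_genes = scale_genes

    def _process(self, X, fitting: bool):
        X = np.asarray(getattr(X, "values", X), dtype=float)
        if self.normalize:
            target = None if fitting else self.library_target_
            totals = X.sum(axis=1)
            if fitting:
                self.library_target_ = float(np.median(totals))
            X = normalize_counts(X, target=self.library_target_)
        if self.log1p:
            X = np.log1p(X)
        return X

    def fit(self, X, y=None):
        X = self._process(X, fitting=True)
        n, G = X.shape
        H = self.n_components
        if not 1 <= H <= min(n - 1, G):
            raise ValueError(f"n_components must lie in [1, {min(n - 1, G)}]")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.scale_genes:
            sd = Xc.std(axis=0, ddof=1)
            self.gene_scale_ = np.where(sd > 0, sd, 1.0)
            Xc = Xc / self.gene_scale_
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
        if H > rank:
            raise ValueError(f"n_components={H} exceeds rank; at most {rank} available")
        comps = Vt[:H]
        flip = np.sign(comps[np.arange(H), np.argmax(np.abs(comps), axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comps * flip[:, None]
        self.explained_variance_ = (S[:H] ** 2) / (n - 1)
        self.n_features_in_ = G
        return self

    def transform(self, X):
        if not hasattr(self, "components_"):
            raise ValueError("ExpressionPCA instance is not fitted yet")
        X = self._process(X, fitting=False)
        Xc = X - self.mean_
        if self.scale_genes:
            Xc = Xc / self.gene_scale_
        return Xc @ self.components_.T


class PottsCellTyper(ClusterMixin, BaseEstimator):
    """Nonparametric Bayesian spatial clusterer.

    Cells are clustered from low-dimensional expression features (rows of
    ``X``) and spatial coordinates, under a Potts prior on the directed
    k-nearest-neighbour graph with stick-breaking external-field weights.
    The number of cell types is learned from the data; ``init_k`` only
    initializes the chain.

    Parameters mirror the model hyperparameters (see ``Hyperparams``) and
    the chain configuration. ``random_state`` seeds the whole chain.

    Attributes
    ----------
    labels_ : (n,) point-estimate labels (1-based).
    n_clusters_ : detected number of cell types.
    beta_samples_, k_trace_ : retained post-burn-in traces.
    accept_rate_ : double-MH acceptance fraction.
    chain_ : the full ChainOutput.
    """

    def __init__(self, *, n_neighbors: int = 6, n_iter: int = 6000,
                 burn_in: int = 3000, init_k: int = 8, thin: int = 1,
                 alpha: float = 1.0, a_beta: float = 1.0, tau2_beta: float = 1.0,
                 a_eta: float = 0.0, b2_eta: float = 10.0, kappa: float = 2.0,
                 tau: float = 1.0, r0: int = 50, tau2_0: float = 0.01,
                 tau2_1: float = 0.01, random_state: int = 0, verbose: int = 0):
        self.n_neighbors = n_neighbors
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.init_k = init_k
        self.thin = thin
        self.alpha = alpha
        self.a_beta = a_beta
        self.tau2_beta = tau2_beta
        self.a_eta = a_eta
        self.b2_eta = b2_eta
        self.kappa = kappa
        self.tau = tau
        self.r0 = r0
        self.tau2_0 = tau2_0
        self.tau2_1 = tau2_1
        self.random_state = random_state
        self.verbose = verbose

    def _hyper(self) -> Hyperparams:
        return Hyperparams(
            a_beta=self.a_beta, tau2_beta=self.tau2_beta, a_eta=self.a_eta,
            b2_eta=self.b2_eta, kappa=self.kappa, tau=self.tau,
            alpha=self.alpha, R0=self.r0, tau2_0=self.tau2_0,
            tau2_1=self.tau2_1,
        )

    def _config(self) -> MCMCConfig:
        return MCMCConfig(n_iter=self.n_iter, burn_in=self.burn_in,
                          seed=self.random_state, init_K=self.init_k,
                          thin=self.thin)

    def fit(self, X, y=None, *, coords=None):
        """Run the sampler on features ``X`` (cells x H) and ``coords`` (n x 2)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a cells x features matrix")
        if coords is None:
            raise ValueError("spatial coordinates are required: fit(X, coords=...)")
        xy = np.asarray(getattr(coords, "xy", coords), dtype=float)
        if xy.shape[0] != X.shape[0]:
            raise ValueError("coords and X disagree on the number of cells")
        graph = build_knn_graph(xy, self.n_neighbors)
        chain = run_mcmc(X.T, graph, self._hyper(), self._config(),
                         verbose=self.verbose)
        labels, k_hat = summarize_labels(chain)
        self.chain_ = chain
        self.labels_ = labels
        self.n_clusters_ = k_hat
        self.beta_samples_ = chain.beta_samples
        self.k_trace_ = chain.K_trace
        self.accept_rate_ = chain.accept_rate
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_

    def diagnostics(self) -> dict:
        if not hasattr(self, "chain_"):
            raise ValueError("PottsCellTyper instance is not fitted yet")
        return chain_diagnostics(self.chain_)
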