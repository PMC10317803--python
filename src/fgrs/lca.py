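"""Latent-class analysis of FGRS vectors via diagonal Gaussian mixtures.

To probe etiologic heterogeneity in a case group, the vector of FGRSs over a
selected set of disorders is modelled as a finite mixture of Gaussians with
class-specific means and diagonal covariances — the continuous-indicator
analogue of classical latent class analysis, with local independence within
class.  Models are fit by expectation-maximization (best of several seeded
k-means++ starts), and the number of classes is chosen by minimum BIC.

If the selected solution's class means are ordered along a single axis
(graded severity), the classes represent quantitative rather than
qualitative differences; qualitatively distinct subtypes would show class
means that are not collinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

VAR_FLOOR = 1e-4
MIN_EFFECTIVE_SIZE_PER_DIM = 1.0  # components thinner than d+1 members are degenerate


@dataclass
class MixtureModel:
    """A fitted diagonal-covariance Gaussian mixture."""

    n_classes: int
    weights: np.ndarray          # (k,)
    means: np.ndarray            # (k, d)
    variances: np.ndarray        # (k, d), diagonal
    log_likelihood: float
    n_obs: int
    n_dims: int
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    dim_names: list[str] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        k, d = self.n_classes, self.n_dims
        return (k - 1) + k * d + k * d

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_parameters

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * np.log(self.n_obs)


def _log_gaussian_diag(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Log density of each row of X under each diagonal Gaussian: (n, k)."""
    n, d = X.shape
    k = means.shape[0]
    out = np.empty((n, k))
    for j in range(k):
        diff2 = (X - means[j]) ** 2 / variances[j]
        out[:, j] = -0.5 * (d * np.log(2 * np.pi) + np.log(variances[j]).sum() + diff2.sum(axis=1))
    return out


def _em_once(
    X: np.ndarray,
    n_classes: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> MixtureModel:
    n, d = X.shape
    if n_classes == 1:
        mu = X.mean(axis=0, keepdims=True)
        var = np.maximum(X.var(axis=0, keepdims=True), VAR_FLOOR)
        ll = float(_log_gaussian_diag(X, mu, var).sum())
        return MixtureModel(
            n_classes=1, weights=np.ones(1), means=mu, variances=var,
            log_likelihood=ll, n_obs=n, n_dims=d, converged=True, n_iter=0,
            loglik_trace=np.array([ll]),
        )
    centers, _ = kmeans_plusplus(
        X, n_clusters=n_classes, random_state=int(rng.integers(2**31 - 1))
    )
    means = centers.copy()
    variances = np.tile(np.maximum(X.var(axis=0), VAR_FLOOR), (n_classes, 1))
    weights = np.full(n_classes, 1.0 / n_classes)
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_dens = _log_gaussian_diag(X, means, variances) + np.log(weights)
        log_norm = logsumexp(log_dens, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_dens - log_norm[:, None])
        if prev > -np.inf and abs(ll - prev) < tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
        nk = resp.sum(axis=0) + 1e-300
        if nk.min() < (d + 1) * MIN_EFFECTIVE_SIZE_PER_DIM:
            converged = False  # collapsed (near-singleton) component
            break
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for j in range(n_classes):
            diff2 = (X - means[j]) ** 2
            variances[j] = np.maximum((resp[:, j] @ diff2) / nk[j], VAR_FLOOR)
    return MixtureModel(
        n_classes=n_classes, weights=weights, means=means, variances=variances,
        log_likelihood=trace[-1], n_obs=n, n_dims=d, converged=converged,
        n_iter=it, loglik_trace=np.array(trace),
    )


def fit_mixture(
    X: np.ndarray | pd.DataFrame,
    n_classes: int,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> MixtureModel:
    """Best-of-``n_starts`` EM fit of a ``n_classes``-component mixture.

    Deterministic given ``seed``.  Raises if no start converges.
    """
    dim_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (cases x score dimensions)")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; drop or impute first")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = np.random.default_rng(seed)
    best: MixtureModel | None = None
    best_any: MixtureModel | None = None
    for _ in range(max(n_starts, 1) if n_classes > 1 else 1):
        model = _em_once(X, n_classes, rng, tol, max_iter)
        if best_any is None or model.log_likelihood > best_any.log_likelihood:
            best_any = model
        if model.converged and (best is None or model.log_likelihood > best.log_likelihood):
            best = model
    if best is None:
        assert best_any is not None
        raise RuntimeError(
            f"EM failed to converge in any of {n_starts} starts "
            f"(k={n_classes}, best loglik {best_any.log_likelihood:.2f})"
        )
    best.dim_names = dim_names
    return best


def select_classes(
    X: np.ndarray | pd.DataFrame,
    max_classes: int = 5,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit 1..max_classes and select by minimum BIC (ties -> fewer classes).

    Returns the chosen model and the full fit table
    (classes, loglik, aic, bic, converged).
    """
    models = []
    for k in range(1, max_classes + 1):
        models.append(fit_mixture(X, k, n_starts=n_starts, seed=seed + k, tol=tol, max_iter=max_iter))
    table = pd.DataFrame(
        {
            "classes": [m.n_classes for m in models],
            "loglik": [m.log_likelihood for m in models],
            "aic": [m.aic for m in models],
            "bic": [m.bic for m in models],
            "converged": [m.converged for m in models],
        }
    )
    best_idx = int(table["bic"].round(10).idxmin())  # idxmin takes the first, i.e. fewest classes
    return models[best_idx], table


def classify(model: MixtureModel, X: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Posterior class probabilities per case (rows sum to 1) plus assignment."""
    X = np.asarray(X, dtype=float)
    log_dens = _log_gaussian_diag(X, model.means, model.variances) + np.log(model.weights)
    log_norm = logsumexp(log_dens, axis=1)
    post = np.exp(log_dens - log_norm[:, None])
    df = pd.DataFrame(post, columns=[f"class_{j}" for j in range(model.n_classes)])
    df["assigned"] = post.argmax(axis=1)
    return df


def means_collinearity(model: MixtureModel) -> float:
    """Fraction of class-mean variance on the leading axis (1 = graded classes)."""
    M = model.means - model.means.mean(axis=0)
    if model.n_classes < 3:
        return 1.0
    s = np.linalg.svd(M, compute_uv=False)
    total = float((s**2).sum())
    return float(s[0] ** 2 / total) if total > 0 else 1.0
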