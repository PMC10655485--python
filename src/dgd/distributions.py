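"""Log densities of the model's building blocks.

The observation model is a negative binomial per gene, parameterized by a
mean ``m`` and a gene-specific dispersion ``r`` (variance ``m + m^2/r``).
The latent space carries a Gaussian mixture whose component means have a
"softball" prior (a mollified uniform distribution over a ball), whose
negative-log diagonal covariances have a Gaussian prior, and whose mixture
weights have a symmetric Dirichlet prior.

All functions operate on numpy arrays and broadcast; gradients needed by the
optimizers are provided alongside the densities because the package performs
its own backpropagation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "nb_log_pmf",
    "nb_log_pmf_grad",
    "softball_log_density",
    "softball_log_normalizer",
    "softball_grad",
    "gmm_log_density",
    "gmm_responsibilities",
    "gmm_param_log_prior",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _validate_counts(k: np.ndarray) -> np.ndarray:
    k = np.asarray(k)
    if not np.issubdtype(k.dtype, np.integer):
        kf = np.asarray(k, dtype=float)
        if np.any(kf != np.floor(kf)):
            raise ValueError("counts must be integers")
        k = kf
    if np.any(k < 0):
        raise ValueError("counts must be nonnegative")
    return np.asarray(k, dtype=float)


def nb_log_pmf(k, m, r):
    """Log pmf of the negative binomial, ``NB(k; m, r)``.

    ``log Γ(k+r) − log k! − log Γ(r) + r·log(r/(r+m)) + k·log(m/(r+m))``,
    evaluated in log space so it stays finite for counts up to 1e7 and
    beyond.

    Parameters
    ----------
    k : array-like of nonnegative int
        Observed counts.
    m : array-like of positive float
        Means.
    r : array-like of positive float
        Dispersions; variance is ``m + m**2 / r``.
    """
    k = _validate_counts(k)
    m = np.asarray(m, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mean m must be positive")
    if np.any(r <= 0):
        raise ValueError("dispersion r must be positive")
    return (
        gammaln(k + r)
        - gammaln(k + 1.0)
        - gammaln(r)
        + r * (np.log(r) - np.log(r + m))
        + k * (np.log(m) - np.log(r + m))
    )


def nb_log_pmf_grad(k, m, r):
    """Gradients of ``nb_log_pmf`` with respect to ``m`` and ``r``.

    Returns ``(d/dm, d/dr)``; shapes broadcast like the inputs.
    """
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    r = np.asarray(r, dtype=float)
    dm = k / m - (k + r) / (r + m)
    dr = (
        digamma(k + r)
        - digamma(r)
        + np.log(r)
        - np.log(r + m)
        + 1.0
        - (k + r) / (r + m)
    )
    return dm, dr


def softball_log_normalizer(dim: int, spread: float) -> float:
    """Negative log volume of the ``dim``-ball of radius ``spread``.

    Used as the normalization constant of the mollified uniform ball; the
    mollified density integrates to slightly more than one for finite
    sharpness, which is irrelevant to optimization and accepted for
    comparability of density values.
    """
    log_volume = (
        0.5 * dim * np.log(np.pi)
        + dim * np.log(spread)
        - gammaln(0.5 * dim + 1.0)
    )
    return -log_volume


def softball_log_density(z, spread: float, sharpness: float):
    """Log density of the softball (mollified uniform ball) prior.

    ``−log V(D, spread) − log(1 + exp(sharpness·(‖z‖/spread − 1)))`` where
    ``V`` is the volume of the D-ball. Depends on ``z`` only through its
    Euclidean norm, hence rotation invariant, and non-increasing in ``‖z‖``.

    ``z`` may be a single vector or a stack of vectors (last axis = D);
    returns one value per vector.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    dim = z.shape[-1]
    norm = np.linalg.norm(z, axis=-1)
    t = sharpness * (norm / spread - 1.0)
    # -log(1+exp(t)) = -softplus(t), computed stably
    mollifier = -(np.logaddexp(0.0, t))
    return softball_log_normalizer(dim, spread) + mollifier


def softball_grad(z, spread: float, sharpness: float):
    """Gradient of ``softball_log_density`` with respect to ``z``."""
    z = np.asarray(z, dtype=float)
    norm = np.linalg.norm(z, axis=-1, keepdims=True)
    t = sharpness * (norm / spread - 1.0)
    sig = 1.0 / (1.0 + np.exp(-t))
    safe_norm = np.where(norm > 0, norm, 1.0)
    return -sig * (sharpness / spread) * z / safe_norm


def _gmm_component_log_densities(z, means, neg_log_var, log_weights):
    """Per-component log ``w_c · N(z; μ_c, diag(exp(−β_c)))``.

    ``z``: (..., D); returns (..., C).
    """
    z = np.asarray(z, dtype=float)
    diff = z[..., None, :] - means  # (..., C, D)
    # variance σ² = exp(−β)  ⇒  1/σ² = exp(β),  log σ² = −β
    quad = np.sum(diff * diff * np.exp(neg_log_var), axis=-1)
    log_det = np.sum(-neg_log_var, axis=-1)  # Σ_d log σ²_cd
    dim = means.shape[-1]
    return log_weights - 0.5 * (dim * _LOG_2PI + log_det + quad)


def gmm_log_density(z, means, neg_log_var, log_weights):
    """Log density of a diagonal-covariance Gaussian mixture at ``z``.

    ``log Σ_c w_c N(z; μ_c, diag(exp(−β_c)))`` via log-sum-exp, stable for
    ``‖z‖`` up to at least 1e3.

    Parameters
    ----------
    z : (..., D) array
    means : (C, D) array of component means μ_c
    neg_log_var : (C, D) array β with per-dimension variance exp(−β)
    log_weights : (C,) array of log mixture weights (must be normalized)
    """
    means = np.asarray(means, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != means.shape[-1]:
        raise ValueError(
            f"latent dimension mismatch: z has {z.shape[-1]}, "
            f"mixture has {means.shape[-1]}"
        )
    comp = _gmm_component_log_densities(z, means, neg_log_var, log_weights)
    return logsumexp(comp, axis=-1)


def gmm_responsibilities(z, means, neg_log_var, log_weights):
    """Posterior component responsibilities γ_c(z) (softmax of the
    per-component log densities); shape (..., C)."""
    comp = _gmm_component_log_densities(z, means, neg_log_var, log_weights)
    comp = comp - logsumexp(comp, axis=-1, keepdims=True)
    return np.exp(comp)


def gmm_param_log_prior(
    means,
    neg_log_var,
    weights,
    spread: float,
    sharpness: float,
    beta_prior_mean: float,
    beta_prior_sd: float,
    dirichlet_alpha: float,
):
    """Log prior over the mixture parameters.

    Sum of the softball log density over every component mean, an
    independent Gaussian log density over every entry of the negative-log
    diagonal covariance, and a symmetric Dirichlet log density over the
    mixture weights.
    """
    means = np.asarray(means, dtype=float)
    neg_log_var = np.asarray(neg_log_var, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n_comp = means.shape[0]

    mean_term = np.sum(softball_log_density(means, spread, sharpness))

    resid = (neg_log_var - beta_prior_mean) / beta_prior_sd
    beta_term = np.sum(
        -0.5 * resid**2 - np.log(beta_prior_sd) - 0.5 * _LOG_2PI
    )

    a = dirichlet_alpha
    log_norm = gammaln(n_comp * a) - n_comp * gammaln(a)
    weight_term = log_norm + (a - 1.0) * np.sum(np.log(weights))

    return mean_term + beta_term + weight_term
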