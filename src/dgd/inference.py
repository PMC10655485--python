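"""Closest-normal representation inference for unseen samples.

With the trained model frozen, each new sample gets one candidate latent
vector per mixture component, initialized at the component mean. Every
candidate is optimized by gradient ascent on the sample's log joint
(reconstruction + latent mixture density) for a short search phase; the
best candidate is then refined further. The refined vector is the
"closest-normal" representation: the point in latent space where the
model of healthy tissue explains the sample best, serving as an in-silico
control for single-sample differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import Adam
from .distributions import (
    gmm_log_density,
    gmm_responsibilities,
    nb_log_pmf,
    nb_log_pmf_grad,
)
from .model import MEAN_FLOOR, DGDModel, decode

__all__ = [
    "InferenceConfig",
    "InferenceResult",
    "infer_representation",
    "assign_component",
    "neg_log_prob_mass",
]


@dataclass
class InferenceConfig:
    """Search/refinement schedule for single-sample inference.

    One candidate is spawned per mixture component; ``search_epochs``
    optimization steps precede best-of selection, ``refine_epochs`` steps
    follow it. The optimizer matches training (Adam, betas 0.5/0.9).
    Setting ``reconstruction_only`` scores and optimizes candidates on the
    NB reconstruction term alone, without the latent density.
    """

    search_epochs: int = 10
    refine_epochs: int = 50
    lr: float = 0.01
    betas: tuple[float, float] = (0.5, 0.9)
    reconstruction_only: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.search_epochs < 0 or self.refine_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class InferenceResult:
    z: np.ndarray  # best refined latent vector (D,)
    component: int  # hard assignment of z
    candidate_objectives: np.ndarray  # (C,) final search-phase objectives
    neg_log_prob_mass: float


def _objectives(model: DGDModel, z_cand, x, scale, reconstruction_only):
    """Log joint (or reconstruction) for candidate rows; higher is better."""
    gmm = model.gmm
    y = model.decoder.forward(z_cand, cache=True)
    m = y * scale + MEAN_FLOOR
    recon = np.sum(nb_log_pmf(x, m, model.dispersion), axis=1)
    if reconstruction_only:
        return recon
    lat = gmm_log_density(z_cand, gmm.means, gmm.neg_log_var, gmm.log_weights)
    return recon + lat


def _ascent_grad(model: DGDModel, z_cand, x, scale, reconstruction_only):
    """Gradient of the (negated) objective with respect to each candidate."""
    gmm = model.gmm
    y = model.decoder.forward(z_cand, cache=True)
    m = y * scale + MEAN_FLOOR
    dll_dm, _ = nb_log_pmf_grad(x, m, model.dispersion)
    grad_z, _, _ = model.decoder.backward(-dll_dm * scale)
    if not reconstruction_only:
        resp = gmm_responsibilities(
            z_cand, gmm.means, gmm.neg_log_var, gmm.log_weights
        )
        prec = np.exp(gmm.neg_log_var)
        diff = z_cand[:, None, :] - gmm.means
        grad_z = grad_z + (resp[:, :, None] * diff * prec).sum(axis=1)
    return grad_z  # gradient of the NEGATIVE objective


def infer_representation(
    x, model: DGDModel, config: InferenceConfig | None = None
) -> InferenceResult:
    """Closest-normal representation of one count vector.

    The procedure is deterministic (all candidates start at component
    means); the model is never modified. If refinement ends with a worse
    objective than it started (overshoot), the pre-refinement vector is
    restored.
    """
    config = config or InferenceConfig()
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape[0] != model.n_genes:
        raise ValueError(f"sample has {x.shape[0]} genes, model expects {model.n_genes}")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    scale = float(x.mean())
    if scale <= 0:
        raise ValueError("all-zero sample: sample scale undefined")

    frozen = model.snapshot()
    z_cand = model.gmm.means.copy()

    opt = Adam([z_cand], config.lr, config.betas)
    for _ in range(config.search_epochs):
        g = _ascent_grad(model, z_cand, x, scale, config.reconstruction_only)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite objective during candidate search")
        opt.step([g])

    obj = _objectives(model, z_cand, x, scale, config.reconstruction_only)
    best = int(np.argmax(obj))
    z_best = z_cand[best : best + 1].copy()
    obj_before = float(obj[best])

    opt = Adam([z_best], config.lr, config.betas)
    for _ in range(config.refine_epochs):
        g = _ascent_grad(model, z_best, x, scale, config.reconstruction_only)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite objective during refinement")
        opt.step([g])

    obj_after = float(
        _objectives(model, z_best, x, scale, config.reconstruction_only)[0]
    )
    if obj_after < obj_before - 1e-6:
        z_best = z_cand[best : best + 1].copy()  # refinement overshot

    for before, after in zip(frozen, model.parameter_arrays()):
        if not np.array_equal(before, after):
            raise RuntimeError("model parameters changed during inference")

    z_final = z_best[0]
    result = InferenceResult(
        z=z_final,
        component=assign_component(z_final, model.gmm),
        candidate_objectives=obj,
        neg_log_prob_mass=np.nan,
    )
    result.neg_log_prob_mass = neg_log_prob_mass(x, result, model)
    return result


def assign_component(z, gmm) -> int:
    """Index of the mixture component with the highest weighted density at
    ``z``; ties resolve to the lowest index."""
    z = np.asarray(z, dtype=float)
    from .distributions import _gmm_component_log_densities

    comp = _gmm_component_log_densities(
        z, gmm.means, gmm.neg_log_var, gmm.log_weights
    )
    return int(np.argmax(comp))


def neg_log_prob_mass(x, result: InferenceResult, model: DGDModel) -> float:
    """Negative log of the sample's total probability mass: the negated sum
    over genes of the NB log pmf at the decoded means of the inferred
    representation. Larger values mean the sample is less well explained
    by the healthy-tissue model."""
    x = np.asarray(x, dtype=float).reshape(-1)
    m = decode(result.z, model, float(x.mean()))
    return float(-np.sum(nb_log_pmf(x, m, model.dispersion)))
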