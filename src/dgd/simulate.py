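"""Synthetic multi-tissue RNA-seq cohorts with known ground truth.

Each tissue owns a latent archetype; a sample's latent vector is its
archetype plus isotropic Gaussian noise. A fixed linear-plus-rectifier
"truth decoder" maps latents to per-gene relative expression, normalized
to mean 1 per sample so the sample's library scale is identifiable as its
mean count. Counts are negative binomial with gene-specific dispersions
drawn log-uniformly. The generator deliberately uses a transparent truth
decoder rather than the full model family: ground-truth means stay
hand-computable, which is what the tests need.

Perturbed ("tumor-like") samples are created by re-drawing designated
genes at a multiplied (or divided) mean — a positive-control analogue of
dysregulated driver genes. Spiked genes default to the well-expressed,
low-dispersion regime where a single-sample test has statistical power:
a fold-4 shift in a gene with biological squared CV above ~20%
(dispersion below ~5) lies within single-sample noise and cannot serve
as a positive control for any method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_samples",
    "spike_sample",
]


@dataclass
class SimConfig:
    """Cohort-generation settings.

    ``separation`` is the minimum pairwise Euclidean distance between
    tissue archetypes in the truth latent space; ``noise_sd`` the
    within-tissue isotropic spread around the archetype. Library scales
    are log-normal; dispersions log-uniform over ``dispersion_range``.
    """

    n_tissues: int = 5
    samples_per_tissue: int = 100
    n_genes: int = 200
    latent_dim: int = 5
    separation: float = 8.0
    noise_sd: float = 0.25
    library_scale_log_mean: float = float(np.log(100.0))
    library_scale_log_sd: float = 0.3
    dispersion_range: tuple[float, float] = (0.5, 20.0)
    n_spiked: int = 20
    spike_fold: float = 4.0
    spike_fraction_up: float = 1.0
    spike_min_profile: float = 0.15
    spike_max_profile: float = 0.9
    spike_min_dispersion: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tissues, self.samples_per_tissue, self.n_genes,
               self.latent_dim, self.n_spiked) < 1:
            raise ValueError("counts must be >= 1")
        if self.separation <= 0 or self.spike_fold <= 0:
            raise ValueError("separation and spike fold must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    tissue: np.ndarray  # (N,) str labels
    latent: np.ndarray  # (N, D_true)
    archetypes: np.ndarray  # (T, D_true)
    profiles: np.ndarray  # (T, G) per-tissue relative expression (mean 1)
    dispersion: np.ndarray  # (G,)
    library_scale: np.ndarray  # (N,)
    mean_matrix: np.ndarray  # (N, G) NB means the counts were drawn from
    spike_eligible: np.ndarray  # (T, G) bool: valid positive-control targets
    decoder_weights: np.ndarray = None  # (D_true, G) truth linear map
    decoder_baseline: np.ndarray = None  # (G,) truth baseline expression
    config: "SimConfig" = None
    spiked: dict[str, dict] = field(default_factory=dict)  # sample → spec

    def to_json_dict(self) -> dict:
        return {
            "tissue": self.tissue.tolist(),
            "archetypes": self.archetypes.tolist(),
            "dispersion": self.dispersion.tolist(),
            "library_scale": self.library_scale.tolist(),
            "spiked": self.spiked,
        }


def _archetypes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Tissue archetypes with controlled pairwise separation.

    When the tissue count fits the latent dimension, archetypes sit on
    orthogonal axes scaled so EVERY pairwise distance equals
    ``separation`` — the cohort's difficulty is then uniform, with no
    random-geometry lottery. Otherwise random draws are rescaled so the
    minimum pairwise distance equals ``separation``.
    """
    if cfg.n_tissues == 1:
        return np.zeros((1, cfg.latent_dim))
    if cfg.n_tissues <= cfg.latent_dim:
        arch = np.zeros((cfg.n_tissues, cfg.latent_dim))
        idx = np.arange(cfg.n_tissues)
        arch[idx, idx] = cfg.separation / np.sqrt(2.0)
        return arch
    a = rng.standard_normal((cfg.n_tissues, cfg.latent_dim))
    d = np.linalg.norm(a[:, None, :] - a[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return a * (cfg.separation / d.min())


def _truth_decoder(rng, cfg: SimConfig):
    """Fixed linear map + rectifier + per-gene baseline for the truth."""
    w = rng.standard_normal((cfg.latent_dim, cfg.n_genes)) / np.sqrt(cfg.latent_dim)
    baseline = rng.uniform(0.05, 0.5, size=cfg.n_genes)
    return w, baseline

def _profiles(latent, w, baseline):
    raw = np.maximum(latent @ w, 0.0) + baseline
    mean = raw.mean(axis=-1, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("degenerate configuration: all-zero expression profile")
    return raw / mean


def simulate_cohort(config: SimConfig | None = None) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a full cohort; deterministic under the configured seed."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    arch = _archetypes(rng, cfg)
    w, baseline = _truth_decoder(rng, cfg)
    dispersion = np.exp(
        rng.uniform(
            np.log(cfg.dispersion_range[0]),
            np.log(cfg.dispersion_range[1]),
            size=cfg.n_genes,
        )
    )

    n = cfg.n_tissues * cfg.samples_per_tissue
    tissue_idx = np.repeat(np.arange(cfg.n_tissues), cfg.samples_per_tissue)
    latent = arch[tissue_idx] + cfg.noise_sd * rng.standard_normal(
        (n, cfg.latent_dim)
    )
    rel = _profiles(latent, w, baseline)  # (N, G), mean 1 per sample
    scale = np.exp(
        cfg.library_scale_log_mean
        + cfg.library_scale_log_sd * rng.standard_normal(n)
    )
    mean_matrix = rel * scale[:, None]
    counts = rng.negative_binomial(
        dispersion, dispersion / (dispersion + mean_matrix)
    )

    tissue_profiles = _profiles(arch, w, baseline)  # (T, G)
    # positive-control targets: moderately expressed genes (so the spike
    # set stays a minor fraction of the library, as in spike-in protocol
    # design) with low biological noise (so a fold-4 shift exceeds
    # single-sample NB scatter)
    eligible = (
        (tissue_profiles >= cfg.spike_min_profile)
        & (tissue_profiles <= cfg.spike_max_profile)
        & (dispersion >= cfg.spike_min_dispersion)
    )

    labels = np.array([f"tissue_{i}" for i in tissue_idx])
    cm = CountMatrix(
        values=counts.astype(np.int64),
        gene_ids=[f"gene_{g}" for g in range(cfg.n_genes)],
        sample_ids=[f"sample_{s}" for s in range(n)],
        tissues=labels.tolist(),
    )
    truth = SyntheticTruth(
        tissue=labels,
        latent=latent,
        archetypes=arch,
        profiles=tissue_profiles,
        dispersion=dispersion,
        library_scale=scale,
        mean_matrix=mean_matrix,
        spike_eligible=eligible,
        decoder_weights=w,
        decoder_baseline=baseline,
        config=cfg,
    )
    return cm, truth


def simulate_samples(
    truth: SyntheticTruth, samples_per_tissue: int, seed: int
) -> tuple[CountMatrix, SyntheticTruth]:
    """Fresh samples from an existing cohort's ground truth.

    Draws new latents around the SAME archetypes and decodes through the
    SAME truth decoder and dispersions — held-out data for testing
    representation inference and single-sample differential expression.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    n = cfg.n_tissues * samples_per_tissue
    tissue_idx = np.repeat(np.arange(cfg.n_tissues), samples_per_tissue)
    latent = truth.archetypes[tissue_idx] + cfg.noise_sd * rng.standard_normal(
        (n, cfg.latent_dim)
    )
    rel = _profiles(latent, truth.decoder_weights, truth.decoder_baseline)
    scale = np.exp(
        cfg.library_scale_log_mean
        + cfg.library_scale_log_sd * rng.standard_normal(n)
    )
    mean_matrix = rel * scale[:, None]
    r = truth.dispersion
    counts = rng.negative_binomial(r, r / (r + mean_matrix))
    labels = np.array([f"tissue_{i}" for i in tissue_idx])
    cm = CountMatrix(
        values=counts.astype(np.int64),
        gene_ids=[f"gene_{g}" for g in range(cfg.n_genes)],
        sample_ids=[f"heldout_{s}" for s in range(n)],
        tissues=labels.tolist(),
    )
    new_truth = SyntheticTruth(
        tissue=labels,
        latent=latent,
        archetypes=truth.archetypes,
        profiles=truth.profiles,
        dispersion=truth.dispersion,
        library_scale=scale,
        mean_matrix=mean_matrix,
        spike_eligible=truth.spike_eligible,
        decoder_weights=truth.decoder_weights,
        decoder_baseline=truth.decoder_baseline,
        config=cfg,
    )
    return cm, new_truth


def spike_sample(
    x,
    truth: SyntheticTruth,
    sample_index: int,
    genes,
    fold: float | None = None,
    up_mask=None,
    seed: int = 0,
) -> np.ndarray:
    """Re-draw the designated genes of one sample at a perturbed mean.

    Each spiked gene's count is re-drawn from its NB with the ground-truth
    mean multiplied by ``fold`` (up) or divided by it (down); all other
    genes are returned bit-identical. ``genes`` holds column indices;
    ``up_mask`` marks which are up-spiked (all, by default).
    """
    genes = np.asarray(genes, dtype=np.int64)
    if genes.size == 0:
        raise ValueError("empty spike gene set")
    fold = float(fold) if fold is not None else 4.0
    if fold <= 0:
        raise ValueError("fold must be positive")
    if up_mask is None:
        up_mask = np.ones(genes.size, dtype=bool)
    rng = np.random.default_rng(seed)

    out = np.asarray(x).copy()
    m = truth.mean_matrix[sample_index, genes] * np.where(
        up_mask, fold, 1.0 / fold
    )
    r = truth.dispersion[genes]
    out[genes] = rng.negative_binomial(r, r / (r + m))
    return out
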