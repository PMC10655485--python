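"""The deep generative decoder model.

A ``DGDModel`` bundles the decoder network, the Gaussian mixture over
latent space, the per-gene negative binomial dispersions and the prior
hyperparameters. There is no encoder: each sample owns a free latent
vector, optimized jointly with the model during fitting and alone at
inference time.

The decoder output for gene g is rectified, scaled by the sample's mean
count across genes, and lifted by a small positive floor; the result is
the NB mean ``m_g``. Dispersions are held on a log scale internally so
gradient updates cannot leave the positive half-line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .decoder import Decoder
from .distributions import gmm_log_density, nb_log_pmf

__all__ = [
    "MEAN_FLOOR",
    "PriorHyperparams",
    "GMMParams",
    "DecoderSpec",
    "DGDModel",
    "decode",
    "sample_log_joint",
    "save_model",
    "load_model",
]

#: positive floor added to decoded NB means so the pmf is defined where the
#: rectifier outputs exactly zero
MEAN_FLOOR = 1e-10

_SCHEMA_VERSION = 1


@dataclass
class PriorHyperparams:
    """Hyperparameters of the priors on the mixture parameters.

    ``spread`` and ``sharpness`` shape the softball prior on component
    means (radius and boundary steepness); ``beta_prior_mean``/``sd``
    parameterize the Gaussian prior on the negative-log diagonal
    covariances; ``dirichlet_alpha`` is the shared concentration of the
    symmetric Dirichlet on mixture weights.
    """

    spread: float = 7.0
    sharpness: float = 10.0
    beta_prior_mean: float = 1.0
    beta_prior_sd: float = 1.0
    dirichlet_alpha: float = 5.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class GMMParams:
    """Gaussian mixture parameters over the latent space.

    ``neg_log_var`` holds β with per-dimension variance ``exp(−β)``;
    mixture weights live as unconstrained logits and are exposed
    normalized.
    """

    means: np.ndarray  # (C, D)
    neg_log_var: np.ndarray  # (C, D)
    weight_logits: np.ndarray  # (C,)

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.means.shape[1]

    @property
    def log_weights(self) -> np.ndarray:
        lw = self.weight_logits - np.max(self.weight_logits)
        return lw - np.log(np.sum(np.exp(lw)))

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def copy(self) -> "GMMParams":
        return GMMParams(
            self.means.copy(), self.neg_log_var.copy(), self.weight_logits.copy()
        )


@dataclass
class DecoderSpec:
    """Architecture of the decoder: latent dim, hidden widths, output =
    gene count; dispersion initial value shared by every gene."""

    latent_dim: int = 50
    hidden: tuple[int, ...] = (500, 8000)
    dispersion_init: float = 2.0

    def widths(self, n_genes: int) -> list[int]:
        if n_genes < 1:
            raise ValueError("gene count must be >= 1")
        return [self.latent_dim, *self.hidden, n_genes]


@dataclass
class DGDModel:
    """Decoder weights + mixture + dispersions + priors + gene IDs."""

    decoder: Decoder
    gmm: GMMParams
    log_dispersion: np.ndarray  # (G,)
    priors: PriorHyperparams
    gene_ids: list[str] = field(default_factory=list)
    spec: DecoderSpec | None = None

    def __post_init__(self):
        if self.gene_ids and len(self.gene_ids) != self.decoder.output_dim:
            raise ValueError("gene-ID list length must equal decoder output width")

    @property
    def n_genes(self) -> int:
        return self.decoder.output_dim

    @property
    def latent_dim(self) -> int:
        return self.decoder.latent_dim

    @property
    def dispersion(self) -> np.ndarray:
        """Per-gene NB dispersion r_g (> 0)."""
        return np.exp(self.log_dispersion)

    def parameter_arrays(self) -> list[np.ndarray]:
        """All trainable arrays (used by the frozen-parameter contract)."""
        return [
            *self.decoder.parameters(),
            self.gmm.means,
            self.gmm.neg_log_var,
            self.gmm.weight_logits,
            self.log_dispersion,
        ]

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self.parameter_arrays()]


def decode(z, model: DGDModel, sample_scale) -> np.ndarray:
    """Per-gene NB means for latent rows ``z``.

    ``m_g = relu(f_θ(z))_g · sample_scale + ε`` with ``ε`` the mean floor;
    ``sample_scale`` is the sample's arithmetic mean count across genes
    (scalar, or one per row of ``z``).
    """
    scale = np.asarray(sample_scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("sample_scale must be positive")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    out = model.decoder.forward(z)
    m = out * scale.reshape(-1, 1) + MEAN_FLOOR
    return m[0] if np.ndim(sample_scale) == 0 and m.shape[0] == 1 else m


def sample_log_joint(x, z, model: DGDModel, sample_scale) -> float:
    """Reconstruction + latent density for one sample.

    ``Σ_g log NB(x_g; m_g(z), r_g) + log p_GMM(z)``: the per-sample part
    of the training objective, and the quantity maximized over ``z`` when
    inferring a representation.
    """
    x = np.asarray(x)
    m = decode(z, model, sample_scale)
    recon = np.sum(nb_log_pmf(x, m, model.dispersion), axis=-1)
    lat = gmm_log_density(
        np.asarray(z, dtype=float),
        model.gmm.means,
        model.gmm.neg_log_var,
        model.gmm.log_weights,
    )
    total = recon + lat
    return float(total) if np.ndim(total) == 0 else total


def save_model(model: DGDModel, path) -> None:
    """Serialize to a single ``.npz`` archive; parameter round-trip is
    bit-exact (float64 stored verbatim)."""
    meta = {
        "schema_version": _SCHEMA_VERSION,
        "gene_ids": list(model.gene_ids),
        "priors": asdict(model.priors),
        "widths": model.decoder.widths,
        "spec": None
        if model.spec is None
        else {
            "latent_dim": model.spec.latent_dim,
            "hidden": list(model.spec.hidden),
            "dispersion_init": model.spec.dispersion_init,
        },
    }
    arrays = {
        "meta": np.array(json.dumps(meta)),
        "gmm_means": model.gmm.means,
        "gmm_neg_log_var": model.gmm.neg_log_var,
        "gmm_weight_logits": model.gmm.weight_logits,
        "log_dispersion": model.log_dispersion,
    }
    for i, w in enumerate(model.decoder.weights):
        arrays[f"decoder_w{i}"] = w
    for i, b in enumerate(model.decoder.biases):
        arrays[f"decoder_b{i}"] = b

    # plain np.savez stamps zip entries with the current time; fixed
    # timestamps keep the archive byte-identical across reruns
    import io as _io
    import zipfile

    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name, arr in arrays.items():
            buf = _io.BytesIO()
            np.save(buf, np.ascontiguousarray(arr))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_model(path) -> DGDModel:
    with np.load(path, allow_pickle=False) as archive:
        meta_arr = np.asarray(archive["meta"]).reshape(-1)
        meta = json.loads(str(meta_arr[0]))
        if meta["schema_version"] != _SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {meta['schema_version']}"
            )
        widths = meta["widths"]
        dec = object.__new__(Decoder)
        dec.widths = list(widths)
        dec.weights = [archive[f"decoder_w{i}"] for i in range(len(widths) - 1)]
        dec.biases = [archive[f"decoder_b{i}"] for i in range(len(widths) - 1)]
        dec._cache = None
        gmm = GMMParams(
            archive["gmm_means"],
            archive["gmm_neg_log_var"],
            archive["gmm_weight_logits"],
        )
        spec = None
        if meta.get("spec"):
            spec = DecoderSpec(
                latent_dim=meta["spec"]["latent_dim"],
                hidden=tuple(meta["spec"]["hidden"]),
                dispersion_init=meta["spec"]["dispersion_init"],
            )
        return DGDModel(
            decoder=dec,
            gmm=gmm,
            log_dispersion=archive["log_dispersion"],
            priors=PriorHyperparams(**meta["priors"]),
            gene_ids=list(meta["gene_ids"]),
            spec=spec,
        )
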