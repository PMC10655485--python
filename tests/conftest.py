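"""Shared fixtures: a tiny model for cheap unit tests and one full
reduced-scale study (simulated cohort + trained model + held-out data)
reused across the training/inference/evaluation/acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from dgd import (
    DecoderSpec,
    InferenceConfig,
    ModelConfig,
    PriorHyperparams,
    SimConfig,
    TrainConfig,
    assign_component,
    association_matrix,
    infer_representation,
    init_model,
    simulate_cohort,
    simulate_samples,
)
from dgd.training import (
    reduced_scale_configs,
    reduced_scale_inference,
    train_with_restarts,
)

STUDY_SEED = 2017


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained small model + representations: G=12, D=3, C=3, N=6."""
    mcfg = ModelConfig(
        spec=DecoderSpec(latent_dim=3, hidden=(6,), dispersion_init=2.0),
        n_components=3,
        priors=PriorHyperparams(),
    )
    model, reps = init_model(12, 6, mcfg, TrainConfig(seed=5))
    return model, reps


@pytest.fixture(scope="session")
def toy_study():
    """The reduced-scale study: 5 tissues x 100 samples x 200 genes,
    trained reduced model, hard assignments, held-out samples."""
    cm, truth = simulate_cohort(SimConfig(seed=STUDY_SEED))
    mcfg, tcfg = reduced_scale_configs(seed=STUDY_SEED + 14)
    model, reps, report, latent_terms = train_with_restarts(
        cm.n_genes, cm, mcfg, tcfg, gene_ids=cm.gene_ids
    )
    assign = np.array([assign_component(z, model.gmm) for z in reps.z])
    assoc = association_matrix(assign, truth.tissue)
    holdout, holdout_truth = simulate_samples(truth, 20, seed=STUDY_SEED + 40)
    return {
        "counts": cm,
        "truth": truth,
        "model": model,
        "representations": reps,
        "report": report,
        "assignments": assign,
        "association": assoc,
        "holdout": holdout,
        "holdout_truth": holdout_truth,
        "train_config": tcfg,
        "model_config": mcfg,
    }


@pytest.fixture(scope="session")
def holdout_inference(toy_study):
    """Inferred representations for every held-out sample (default
    search+refine schedule)."""
    model = toy_study["model"]
    ho = toy_study["holdout"]
    cfg = InferenceConfig()
    return [infer_representation(ho.values[i], model, cfg) for i in range(ho.n_samples)]


@pytest.fixture(scope="session")
def de_inference_config():
    return reduced_scale_inference()
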