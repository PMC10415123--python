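"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nptrap import synthetic_data as sd

settings.register_profile("ci", max_examples=30, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_models():
    models = sd.generate_transcriptome(40, seed=1)
    return sd.assign_regulation(
        models,
        {"null": 0.6, "forwarded": 0.1, "exclusive": 0.1, "intensified": 0.1,
         "buffered": 0.1},
        effect_size_log2=2.0, seed=2)


@pytest.fixture(scope="session")
def small_design():
    return sd.SimDesign(library_size=40_000, dispersion=0.05, p_conv=0.1,
                        p_err=0.001, seed=3)


@pytest.fixture(scope="session")
def small_counts(small_models, small_design):
    tables, truth = sd.simulate_counts(small_models, small_design, seed=3)
    return tables, truth


def uniform_models(n_genes, n_uridines=20, k_deg=0.3, seed=0, **kwargs):
    """Genes with identical uridine content and turnover, for analytic oracles."""
    models = sd.generate_transcriptome(n_genes, seed=seed, **kwargs)
    return [replace(m, n_uridines_per_read=n_uridines, k_deg=k_deg) for m in models]


def nb_counts(rng, mean, dispersion, shape=None):
    """NB draws with the package's (mean, dispersion) parameterization."""
    mean = np.broadcast_to(mean, shape) if shape is not None else np.asarray(mean)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def two_group_meta(n_per_group=3, assay="rna", prefix="s"):
    samples = [f"{prefix}{i}" for i in range(2 * n_per_group)]
    return pd.DataFrame(
        {
            "condition": ["control"] * n_per_group + ["stress"] * n_per_group,
            "assay": assay,
            "replicate": list(range(1, n_per_group + 1)) * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
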