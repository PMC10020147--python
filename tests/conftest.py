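import warnings

import numpy as np
import pandas as pd
import pytest

from rangeocc.model import MCMCSettings
from rangeocc.pipeline import PipelineConfig, run_pipeline
from rangeocc.synth import SynthConfig, generate_metadataset

warnings.filterwarnings("ignore", message="ArviZ is undergoing")


@pytest.fixture(scope="session")
def small_metadataset():
    """A 6-study metadataset shared across tests (fixed seed)."""
    cfg = SynthConfig(n_studies=6, n_species_per_study=20, seed=11)
    surveys, truth = generate_metadataset(cfg)
    return cfg, surveys, truth


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """A full small pipeline run (all stages, short MCMC)."""
    out = tmp_path_factory.mktemp("pipe")
    cfg = PipelineConfig(
        synth=SynthConfig(n_studies=6, n_species_per_study=20, seed=7),
        seed=7, rarefaction_iterations=4, fit_iterations=1,
        mcmc=MCMCSettings(n_steps=800, n_burn=400, seed=7),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run_pipeline(cfg, out)
    return cfg, bundle


def presence_table(records):
    """Helper: presence rows (site, year, species) -> DataFrame."""
    return pd.DataFrame(records, columns=["site_id", "year", "species_id"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
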