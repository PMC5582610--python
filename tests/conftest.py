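"""Shared fixtures: small planted studies generated once per session."""

import numpy as np
import pandas as pd
import pytest

import partsig as ps


@pytest.fixture(scope="session")
def small_study():
    """A 600-gene planted study (effect 2.0) with its z-scores and truth."""
    design = ps.default_design(n_genes=600, seed=7)
    truth = ps.default_truth(design, effect=2.0)
    study = ps.generate_study(design, truth)
    z = ps.zscore_normalize(study)
    return study, z, truth


@pytest.fixture(scope="session")
def null_study():
    """Same design with zero effect everywhere: no class signal."""
    design = ps.default_design(n_genes=600, seed=7)
    truth = ps.default_truth(design, effect=0.0)
    study = ps.generate_study(design, truth)
    z = ps.zscore_normalize(study)
    return study, z, truth


@pytest.fixture(scope="session")
def motif_bench():
    """Planted motif benchmark: profile, sequences, truth."""
    return ps.motif_benchmark(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
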