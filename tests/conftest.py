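"""Shared fixtures: synthetic datasets reused across the suite.

The expensive objects (the clean 2 x 2000-nucleus lobule and its diffusion
pseudodistance) are session-scoped so they are simulated and embedded once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hepzone.io import MarkerSets
from hepzone.pseudodistance import compute_dpd
from hepzone.qc import normalize_log
from hepzone.simulate import LobuleSimConfig, generate_lobule_counts


@pytest.fixture(scope="session")
def clean_lobule():
    """Unperturbed lobule (no KO effect): both genotypes share the zonation
    gradients, so the latent coordinate is recoverable for every nucleus."""
    config = LobuleSimConfig(seed=1, ko_effect={})
    adata, truth = generate_lobule_counts(config)
    return adata, truth


@pytest.fixture(scope="session")
def clean_norm(clean_lobule):
    adata, _ = clean_lobule
    return normalize_log(adata)


@pytest.fixture(scope="session")
def markers80():
    """Marker sets built from the simulated panel's monotone gene classes."""
    return MarkerSets(pericentral=[f"PCg{i:03d}" for i in range(80)],
                      periportal=[f"PPg{i:03d}" for i in range(80)])


@pytest.fixture(scope="session")
def clean_dpd(clean_norm, markers80):
    """End-to-end diffusion pseudodistance on the clean lobule."""
    return compute_dpd(clean_norm, markers80)


@pytest.fixture(scope="session")
def table1_counts():
    """Published genotype-by-case aggregate counts used as a worked input."""
    return pd.DataFrame({"dosage": [0, 1, 2],
                         "n": [54649, 44178, 9192],
                         "cases": [2353, 2508, 698]})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
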