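"""Shared fixtures: synthetic study datasets built once per session."""

import numpy as np
import pytest

from emscore import classify, features, holography, simulate


@pytest.fixture(scope="session")
def study_config():
    """Default four-population configuration at the study's seed."""
    return simulate.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def feature_table(study_config):
    """Feature table of all four default populations (1295 cells)."""
    fields = []
    for profile in study_config.line_profiles:
        pm, gt = simulate.generate_field(study_config, profile.name)
        hm = holography.phase_to_height(pm)
        fields.append((f"{profile.name}-f0", profile.name, hm, gt))
    return features.build_feature_table(fields)


@pytest.fixture(scope="session")
def archetype_split(feature_table):
    """(train, test) partition of the two archetype lines, 80 held out each."""
    arch = feature_table[feature_table["line"].isin(["GIE", "HGF"])]
    return classify.partition_data(arch, test_n=80, seed=1)


@pytest.fixture(scope="session")
def trained_model(archetype_split):
    """EM model bundle trained on the default archetype training set."""
    train, _ = archetype_split
    return classify.train_em_model(train, k=6, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
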