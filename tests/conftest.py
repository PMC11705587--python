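"""Shared fixtures: the default synthetic world, simulated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import lungspectra as ls
from lungspectra.gating import GateTreeClassifier, marker_frame
from lungspectra.simulate import CELL_SHIFTED_DEFAULT, cell_variant
from lungspectra.unmix import build_mixing_matrix, unmix_ols

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def panel():
    return ls.default_panel()


@pytest.fixture(scope="session")
def profiles():
    return ls.default_lung_profiles()


@pytest.fixture(scope="session")
def endmembers():
    return ls.default_endmembers(seed=7)


@pytest.fixture(scope="session")
def af_truth(panel, endmembers):
    return [endmembers[n] for n in endmembers if n not in panel.fluorochromes]


@pytest.fixture(scope="session")
def fluor_sigs(panel, endmembers):
    return [endmembers[f] for f in panel.fluorochromes]


@pytest.fixture(scope="session")
def true_matrix(panel, endmembers, af_truth):
    """Endmember matrix matching the stained (cell-carrier) sample."""
    sigs = [
        cell_variant(endmembers[f]) if f in CELL_SHIFTED_DEFAULT else endmembers[f]
        for f in panel.fluorochromes
    ]
    return build_mixing_matrix(sigs, af_truth)


@pytest.fixture(scope="session")
def default_sample(panel, profiles, endmembers):
    """The standard 17-population sample: n=20,000, default noise, fixed seed."""
    weights = np.full(len(profiles), 1.0 / len(profiles))
    return ls.simulate_sample(
        profiles, weights, panel, endmembers, ls.NoiseModel(), 20_000, seed=DEFAULT_SEED
    )


@pytest.fixture(scope="session")
def default_unmixed(default_sample, true_matrix):
    return unmix_ols(default_sample, true_matrix)


@pytest.fixture(scope="session")
def default_frame(default_unmixed, default_sample, panel):
    return marker_frame(default_unmixed, default_sample.scatter, panel)


@pytest.fixture(scope="session")
def fitted_classifier(default_frame, default_sample):
    return GateTreeClassifier().fit(default_frame, default_sample.truth_labels)


@pytest.fixture(scope="session")
def default_unstained(profiles, af_truth):
    return ls.simulate_unstained(profiles, af_truth, ls.NoiseModel(), 6_000, seed=DEFAULT_SEED)
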