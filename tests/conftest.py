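"""Shared fixtures: small synthetic datasets and the two end-to-end
feedback experiments (run once per session, reused by several tests)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from emloop import picking, simdata
from emloop.protocols import recovery_experiment, steering_experiment
from emloop.types import Micrograph


def movies_to_micrographs(movies):
    return [Micrograph(m.frames[0], micrograph_id=m.micrograph_id)
            for m in movies]


@pytest.fixture(scope="session")
def one_class_dataset():
    """30 single-frame micrographs of one particle species, with truth."""
    specs = simdata.default_class_specs(abundances=(1.0,), kinds=("disc",))
    cfg = simdata.SimConfig(seed=1, particles_per_micrograph=25)
    movies, truth = simdata.generate_dataset(cfg, 30, specs)
    return movies_to_micrographs(movies), truth, specs, cfg


@pytest.fixture(scope="session")
def two_class_dataset():
    """25 micrographs of the 81%/19% disc/ring mixture, with truth."""
    specs = simdata.default_class_specs()
    cfg = simdata.SimConfig(seed=3, particles_per_micrograph=25)
    movies, truth = simdata.generate_dataset(cfg, 25, specs)
    return movies_to_micrographs(movies), truth, specs, cfg


@pytest.fixture(scope="session")
def trained_picker(one_class_dataset):
    """Picker trained on the ground truth of 20 micrographs."""
    mics, truth, specs, _ = one_class_dataset
    labeled = [(m, truth[m.micrograph_id].boxes(specs[0].diameter))
               for m in mics[:20]]
    return picking.train_picker(labeled, seed=0)


@pytest.fixture(scope="session")
def recovery_run():
    """The corrupted-picks recovery experiment (≈1 min, reused)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return recovery_experiment()


@pytest.fixture(scope="session")
def steering_run():
    """The subpopulation-steering experiment (≈1.5 min, reused)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return steering_experiment()
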