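"""Shared fixtures.

The expensive artifacts — the reference phantom cohort, the trained
patch classifier, the activation-maximization stability report and the
cross-validated evaluation — are built once per session and shared by
every test that needs a converged model, so the suite trains the
network only twice (once directly, once inside the cross-validation
harness's folds).
"""

from __future__ import annotations

import numpy as np
import pytest

from amcl import evaluation, netpos, phantom, preprocess
from amcl.activation_max import mean_pib, pib_stability_report

COHORT_SEED = 11
TRAIN_SEED = 0


@pytest.fixture(scope="session")
def cohort():
    """The emulated study cohort: 34 phantoms from 19 patients."""
    return phantom.make_reference_cohort(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def positive_images(cohort):
    return [(i, l) for i, l in cohort if i.contrast_class == "positive"]


@pytest.fixture(scope="session")
def negative_images(cohort):
    return [(i, l) for i, l in cohort if i.contrast_class == "negative"]


@pytest.fixture(scope="session")
def block_dataset(positive_images):
    return preprocess.build_dataset(positive_images, "positive_only",
                                    max_pos_per_rotation=20, seed=0)


@pytest.fixture(scope="session")
def trained_model(block_dataset):
    model, history = netpos.fit_blocks(
        block_dataset, netpos.TrainConfig(seed=TRAIN_SEED))
    assert history[-1] < history[0]
    return model


@pytest.fixture(scope="session")
def lesion_stability(trained_model):
    """Five activation-maximization runs for the lesion target."""
    return pib_stability_report(trained_model, "lesion", 5)


@pytest.fixture(scope="session")
def lesion_pib(trained_model, lesion_stability):
    return mean_pib(lesion_stability["pibs"][:4], trained_model)


@pytest.fixture(scope="session")
def loocv_result(cohort):
    """Full leave-one-patient-out evaluation of both localizers."""
    cfg = evaluation.LoocvConfig(max_pos_per_rotation=20, seed=0)
    return evaluation.loocv_evaluate(cohort, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
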