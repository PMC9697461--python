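"""Shared fixtures: smoke-scale phantom sets and trained smoke models.

The expensive session fixtures (two trained U-Nets) are shared between the
segmentation tests, the pipeline tests and the acceptance suite so training
happens once per run.
"""

import numpy as np
import pytest
from hypothesis import settings

import mandifrac as mf
from mandifrac import pipeline, segnet

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

SMOKE_SEED = 0


@pytest.fixture(scope="session")
def smoke_cfg():
    return pipeline.smoke_phantom_config(SMOKE_SEED)


@pytest.fixture(scope="session")
def train_set(smoke_cfg):
    """40 phantom (image, GroundTruth) pairs for smoke training."""
    return [mf.generate_phantom(smoke_cfg, 1000 + i) for i in range(40)]


@pytest.fixture(scope="session")
def held_out(smoke_cfg):
    """30 held-out phantoms, disjoint seeds from the training set."""
    return [mf.generate_phantom(smoke_cfg, 5000 + i) for i in range(30)]


@pytest.fixture(scope="session")
def smoke_models(train_set):
    """Fracture-line and tooth-region U-Nets trained with the smoke recipe."""
    frac, tooth, frac_hist, tooth_hist = pipeline.train_smoke_models(
        [(im, gt.line_mask) for im, gt in train_set],
        [(im, gt.tooth_mask) for im, gt in train_set],
        seed=SMOKE_SEED)
    return {"fracture": frac, "tooth": tooth,
            "fracture_history": frac_hist, "tooth_history": tooth_hist}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
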