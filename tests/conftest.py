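"""Shared fixtures.

Heavy end-to-end artifacts (trained models plus their concept
extractions) are session-scoped so the bias-recovery checks and the
acceptance tests share one training run per study configuration.  The
two shortcut-bias runs use desk-scale settings (96 px tiles, 30
slides); the seed-replication checks use a reduced scale where the
tissue signal is still reliably learnable.
"""

import numpy as np
import pytest

from xbias import cnn, experiments as ex, synthgen as sg


# seed-replication scale for direction-only checks over several seeds
REPLICATION_SCALE = ex.ScaleConfig(tile_size=80, n_slides=16, tiles_per_slide=16,
                                   max_epochs=25, ratio_epochs=25, tcav_runs=20,
                                   ace_tiles=14, eval_cap=60, min_members=10,
                                   min_tiles=4, n_counterexamples=30)

# desk-scale fixture setting: full desk tile size and slide count with a
# slightly reduced tile count per slide
TEST_DESK = ex.ScaleConfig(tile_size=96, n_slides=30, tiles_per_slide=30,
                           max_epochs=35, ratio_epochs=30, tcav_runs=20,
                           ace_tiles=30, eval_cap=100, min_members=20,
                           min_tiles=5, n_counterexamples=40)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_model():
    """Small untrained network (random weights) for shape/gradient tests."""
    return cnn.build_model(cnn.ModelSpec(input_size=32), seed=7)


class TrainedRun:
    """A trained biased model with its dataset and explanations."""

    def __init__(self, name: str, scale: ex.ScaleConfig, seed: int):
        self.scale = scale
        self.seeds = ex.derive_seeds(seed)
        params = sg.GenParams(tile_size=scale.tile_size)
        self.dataset = sg.build_dataset(ex._bias_for(name, scale),
                                        scale.n_slides, scale.tiles_per_slide,
                                        self.seeds["data"], params)
        self.model, self.history = ex._train_on(self.dataset, scale, name,
                                                self.seeds["train"])
        xte, yte = sg.tiles_to_arrays(self.dataset.test)
        self.metrics = cnn.evaluate(self.model, xte, yte)
        self.extraction, self.tcav_results = ex.explain(
            self.model, self.dataset, scale, self.seeds)


@pytest.fixture(scope="session")
def marker_run():
    """Desk-scale class-correlated-bias run: red square planted on every
    positive tile, model trained until it adopts the shortcut."""
    return TrainedRun("class_correlated", TEST_DESK, seed=1)


@pytest.fixture(scope="session")
def measurement_run():
    """Desk-scale measurement-bias run: label perfectly confounded with
    the source appearance regime."""
    return TrainedRun("measurement", ex.DESK, seed=1)
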