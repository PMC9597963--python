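"""Shared fixtures: small synthetic screens and trained models.

Everything is generated programmatically at collection time from the
synthetic-data module; session scope amortises the cost of training.
"""

import numpy as np
import pytest

import crisprboost as cb

# The two worked example sequences used throughout the tests:
# a human screen guide and a zebrafish screen guide.
SEQ_A = "GTCTGCCATCTCTGATGGATGTGATGGGCA"
SEQ_B = "GGGGGGACTGTATCGACGCTGAATTGGGGG"


@pytest.fixture(scope="session")
def stub_engine():
    return cb.HashStubEngine()


@pytest.fixture(scope="session")
def small_screen(stub_engine):
    """400-guide synthetic screen, featurized with the stub folding engine."""
    cfg = cb.GeneratorConfig(n_guides=400, seed=3)
    ds, signal = cb.simulate_dataset(cfg)
    targets = [cb.validate_target(s) for s in ds.frame.sequence30]
    thermos = cb.compute_thermo_many(targets, engine=stub_engine)
    X = cb.featurize_frame(targets, thermos)
    y = ds.frame.efficiency.to_numpy()
    return {"dataset": ds, "signal": signal, "targets": targets, "X": X, "y": y}


@pytest.fixture(scope="session")
def small_model(small_screen):
    """Model trained without row/column subsampling (exact mean properties)."""
    hp = cb.HyperParams(bagging_fraction=1.0, feature_fraction=1.0)
    cv = cb.CVConfig(k_folds=5, max_trees=100)
    return cb.train_final(small_screen["X"], small_screen["y"], hp, [40] * 5, cv=cv)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
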