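import numpy as np
import pytest

from skinseg import (
    NetworkConfig,
    TilingConfig,
    TrainingConfig,
    build_network,
    train,
)
from skinseg.pipeline import build_tile_dataset
from skinseg.synthetic import StyleParams, generate_cohort

DESK_TILING = TilingConfig(tile_size_um=256.0, min_overlap_um=75.0, mpp=1.0)
DESK_MIN_SECTION = 0.005  # mm^2; desk-scale sections are ~0.05 mm^2


@pytest.fixture(scope="session")
def quick_cohort(tmp_path_factory):
    """Ten fully separable BD/SK slides shared across the session."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(
        10, {"BD": 0.5, "SK": 0.5}, StyleParams(), seed=42, outdir=out,
        separability=1.0, split_label="train")
    return manifest


@pytest.fixture(scope="session")
def quick_dataset(quick_cohort):
    return build_tile_dataset(quick_cohort, DESK_TILING, DESK_MIN_SECTION)


@pytest.fixture(scope="session")
def trained_state(quick_dataset):
    """One desk-scale trained model reused by every inference test."""
    net = build_network(NetworkConfig(input_side=256, preset="small", seed=0))
    state, history = train(
        quick_dataset, net,
        TrainingConfig(learning_rate=1e-3, epochs=10, batch_size=8, seed=0))
    return state, history
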