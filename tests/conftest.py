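import numpy as np
import pytest

from neurofuse.features import FeatureSet, ModelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_feature_set(
    X_layers, name="model", modality="vision", trained=True, encoder_side=None
):
    n = X_layers[0].shape[0]
    return FeatureSet(
        model=ModelSpec(name, "toy", modality, trained, encoder_side),
        layers={f"layer{i}": X for i, X in enumerate(X_layers)},
        event_ids=[f"ev{i:04d}" for i in range(n)],
    )
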