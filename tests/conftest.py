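import numpy as np
import pytest

from busynth import phantom


@pytest.fixture(scope="session")
def benign_masks():
    """200 benign phantom masks at 64x64 (shared across tests)."""
    spec = phantom.default_spec("benign", 64)
    return np.stack([phantom.generate_mask(spec, np.random.default_rng(i)) for i in range(200)])


@pytest.fixture(scope="session")
def phantom_pairs():
    """64 phantom image/mask pairs at 64x64, classes interleaved."""
    out = []
    for i in range(32):
        for label in ("benign", "malignant"):
            spec = phantom.default_spec(label, 64)
            out.append(phantom.generate_pair(spec, np.random.default_rng(1000 + 2 * i + (label == "malignant"))))
    return out
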