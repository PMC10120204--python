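import numpy as np
import pytest

import endofew as ef


@pytest.fixture(scope="session")
def polyp_ds():
    """Small two-class polyp set at desk scale (20 polyps/class, 32 px)."""
    spec = ef.SyntheticPolypSpec.default(20, pattern_contrast=0.8,
                                         image_size=32, seed=11)
    ds, gt = ef.generate_polyp_set(spec)
    return ds, gt


@pytest.fixture(scope="session")
def texture_corpus():
    return ef.generate_texture_corpus(4, 10, 0.25, seed=3, image_size=32)


@pytest.fixture(scope="session")
def tiny_encoder():
    return ef.build_encoder((4, 8), embedding_dim=8, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


class ScriptedRng:
    """Stands in for a Generator where a test must force random draws."""

    def __init__(self, uniforms=(), integers=()):
        self._u = list(uniforms)
        self._i = list(integers)

    def random(self):
        return self._u.pop(0)

    def uniform(self, lo, hi, size=None):
        v = self._u.pop(0)
        val = lo + (hi - lo) * v
        return val if size is None else np.full(size, val)

    def integers(self, *args, **kw):
        return self._i.pop(0)

    def normal(self, loc, scale, size=None):
        return np.zeros(size) if size is not None else 0.0


@pytest.fixture()
def scripted_rng():
    return ScriptedRng
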