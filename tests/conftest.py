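import numpy as np
import pytest

from houghsynteny import OrthologPoint


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_points(rng, n, x_range=(60.0, 100.0), y_range=(0.0, 30.0)):
    """Uniform dot-plot points at the coordinate scale the method targets:
    a ~40-Mb query region against a ~30-Mb target chromosome."""
    xs = rng.uniform(*x_range, size=n)
    ys = rng.uniform(*y_range, size=n)
    return [OrthologPoint(f"g{i}", float(x), float(y)) for i, (x, y) in enumerate(zip(xs, ys))]
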