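import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_atlas():
    """3 genes x 3 tissues with one constant row."""
    from herborgan.expression_linking import ExpressionAtlas

    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [10.0, 0.0, 0.0]],
        index=["g1", "g2", "g3"],
        columns=["t1", "t2", "t3"],
    )
    return ExpressionAtlas(frame)


@pytest.fixture
def random_atlas():
    """50 x 10 strictly positive atlas, seeded."""
    from herborgan.expression_linking import ExpressionAtlas

    rng = np.random.default_rng(42)
    frame = pd.DataFrame(
        rng.lognormal(3.0, 1.0, size=(50, 10)),
        index=[f"g{i}" for i in range(50)],
        columns=[f"t{j}" for j in range(10)],
    )
    return ExpressionAtlas(frame)


@pytest.fixture
def tiny_catalog():
    from herborgan.io_formats import Catalog

    universe = frozenset(f"G{i}" for i in range(100))
    return Catalog(
        terms={
            "liver": frozenset(f"G{i}" for i in range(10)),
            "kidney": frozenset(f"G{i}" for i in range(5, 25)),
            "blood": frozenset(f"G{i}" for i in range(40, 80)),
        },
        universe=universe,
    )
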