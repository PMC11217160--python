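import numpy as np
import pandas as pd
import pytest

from cemdrift.synthetic import (
    DriftSchedule,
    FeatureSpec,
    GeneratorConfig,
    generate_cohort,
    nacsa_like_config,
)

#: canonical suite seed, fixed up front
SEED = 0


@pytest.fixture(scope="session")
def small_cohort():
    """12 stationary registry-like months at modest volume."""
    cfg = nacsa_like_config(n_per_month=400, start_month="2017-01",
                            end_month="2017-12", seed=SEED)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def simple_config():
    """A 3-feature generator with hand-set coefficients for focused tests."""
    return GeneratorConfig(
        n_per_month=500,
        start_month="2017-01",
        end_month="2017-06",
        features=(
            FeatureSpec("urgent", "binary", levels=("no", "yes"), probs=(0.67, 0.33)),
            FeatureSpec("severity", "ordinal", levels=("a", "b", "c"),
                        probs=(0.5, 0.3, 0.2)),
            FeatureSpec("age", "continuous", mean=65.0, sd=10.0, lower=18, upper=100),
        ),
        coefficients={"urgent": 1.0, "severity": 0.5, "age": 0.04},
        base_mortality=0.05,
        seed=SEED,
    )


def rng(offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(SEED + offset)


@pytest.fixture
def random_predictions():
    """A moderately informative random prediction set."""
    g = rng(1)
    n = 400
    p = g.beta(1.2, 8.0, size=n)
    y = (g.random(n) < np.clip(p * 1.5, 0, 1)).astype(int)
    if y.sum() < 2:  # pragma: no cover - guard, not expected at this seed
        y[:2] = 1
    return p, y
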