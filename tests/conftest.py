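import datetime as dt

import numpy as np
import pandas as pd
import pytest

from oge.synthetic import PolicyEffectSpec, ScenarioSpec


@pytest.fixture(scope="session")
def tiny_spec() -> ScenarioSpec:
    """Three cities, seven weeks, modest volume: fast but non-degenerate."""
    return ScenarioSpec(
        n_cities=3,
        start=dt.date(2020, 2, 26),
        end=dt.date(2020, 4, 15),
        volume_mean=60,
        policy_effects=(
            PolicyEffectSpec(k=1, effect=-0.8),
            PolicyEffectSpec(
                k=4, effect=-0.4,
                start=dt.date(2020, 3, 23), end=dt.date(2020, 4, 10),
            ),
        ),
    )


@pytest.fixture(scope="session")
def tiny_posts(tiny_spec):
    from oge.synthetic import generate_posts

    return generate_posts(tiny_spec, seed=7)


@pytest.fixture
def posts_csv(tmp_path):
    """A small hand-written posts file."""
    path = tmp_path / "posts.csv"
    path.write_text(
        "post_id,date,city,sentiment,text\n"
        "a1,2020-03-01,Austin,Positive,trump extended the lockdown\n"
        "a2,2020-03-01,Austin,negative,nice weather today\n"
        "a3,2020-03-02,Boston,mixed,chinatown is quiet\n"
    )
    return path


def ar1(rng: np.random.Generator, n: int, phi: float = 0.5, sd: float = 1.0) -> np.ndarray:
    """Stationary AR(1) path starting from the stationary distribution."""
    e = rng.standard_normal(n) * sd
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


@pytest.fixture(scope="session")
def ar1_factory():
    return ar1
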