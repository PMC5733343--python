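import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from salixfate.io import Channel, FeatureTable, make_design

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    from salixfate.annotate import load_library

    return load_library()


def random_feature_table(rng: np.random.Generator, n_features: int = 10) -> FeatureTable:
    """A random small table over the standard design, with ND patterns.

    Each (feature, cell) gets either a full triplicate around a random
    level, a partially-detected triplicate, or a fully absent cell, so
    that every triage branch (matrix, fast, insufficient, intermediate,
    monotone, unchanged) is reachable.
    """
    design = make_design()
    ids = [f"F{i:03d}" for i in range(1, n_features + 1)]
    areas = pd.DataFrame(
        np.nan, index=pd.Index(ids, name="feature_id"), columns=design.index
    )
    cells = design.groupby(
        ["channel", "wbe_concentration", "time_h"], sort=True
    ).groups
    for fid in ids:
        for _, samples in cells.items():
            kind = rng.choice(["full", "partial", "absent"], p=[0.55, 0.2, 0.25])
            if kind == "absent":
                continue
            level = 10 ** rng.uniform(3, 6)
            values = level * rng.lognormal(0.0, 0.4, size=len(samples))
            if kind == "partial":
                k = rng.integers(1, len(samples))
                values[rng.choice(len(samples), size=len(samples) - k, replace=False)] = np.nan
            areas.loc[fid, list(samples)] = values
    features = pd.DataFrame(
        {
            "mz": rng.uniform(100, 900, size=n_features),
            "rt": rng.uniform(1, 40, size=n_features),
        },
        index=areas.index,
    )
    return FeatureTable(features=features, areas=areas, design=design)
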