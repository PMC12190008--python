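import numpy as np
import pandas as pd
import pytest

from mdiva import (
    FeatureTable,
    MassDifference,
    MassDifferenceList,
    SimulationConfig,
    build_mdin,
    project_edges,
    simulate_study,
)


@pytest.fixture
def water_ladder():
    """Three features spaced by known reaction deltas: 100.0 -> +H2O ->
    118.0106 -> +CO2 -> 162.0368, with two samples."""
    masses = pd.Series([100.0, 118.0106, 162.0368], index=["f1", "f2", "f3"])
    intensities = pd.DataFrame(
        {"s1": [4.0, 9.0, 16.0], "s2": [1.0, 0.0, 25.0]}, index=masses.index
    )
    return FeatureTable(masses, intensities)


@pytest.fixture
def small_md_list():
    return MassDifferenceList(
        [
            MassDifference("water", 18.0106, None, frozenset({"a", "b"})),
            MassDifference("co2", 44.0262, None, frozenset({"c"})),
        ]
    )


@pytest.fixture(scope="session")
def study():
    """One deterministic synthetic study shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_features=200, n_samples_per_group=3)
    bundle = simulate_study(cfg)
    net = build_mdin(bundle.features, bundle.md_list, cfg.tolerance)
    U = project_edges(net)
    return bundle, net, U
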