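import numpy as np
import pandas as pd
import pytest

from moltox import FeatureTable, Molecule, toy_molecule_panel
from moltox.synthdata import PlantedSpec, make_classification_table


@pytest.fixture(scope="session")
def panel():
    return toy_molecule_panel()


@pytest.fixture
def ethanol():
    return Molecule(id="eth", name="ethanol", smiles="CCO")


@pytest.fixture(scope="session")
def small_planted():
    """100 x 30 planted-signal table: 5 informative, strong effect."""
    spec = PlantedSpec(
        n_pos=60, n_neg=40, n_informative=5, n_noise=25, effect_size=2.0, seed=11
    )
    return make_classification_table(spec)


def manual_table(values: dict[str, list[float]], labels=None, kind="descriptor"):
    """Small literal FeatureTable helper for hand-computed cases."""
    X = pd.DataFrame(values, dtype=float)
    X.index = pd.Index([f"m{i}" for i in range(len(X))], name="id")
    lab = None if labels is None else pd.Series(labels, index=X.index)
    return FeatureTable(X, {c: kind for c in X.columns}, lab)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
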