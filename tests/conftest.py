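import numpy as np
import pandas as pd
import pytest

import traitscape as tc


@pytest.fixture(scope="session")
def mini_study():
    """A small synthetic study shared by read-only tests."""
    cfg = tc.desk_preset(
        seed=7, plot_width=100.0, plot_height=100.0, n_species=30, n_stems=2_000
    )
    return tc.generate_study(cfg)


@pytest.fixture
def toy_census(tmp_path):
    """Three valid stems in a 10 x 10 m plot, written as CSV."""
    path = tmp_path / "census.csv"
    pd.DataFrame(
        {
            "stem_id": ["a", "b", "c"],
            "x": [0.0, 4.9, 7.5],
            "y": [0.0, 4.9, 2.5],
            "species": ["sp1", "sp2", "sp1"],
            "dbh": [2.0, 1.0, 10.0],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def traits5():
    """Five species, two standardized-scale traits (plain numbers)."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.normal(size=(5, 2)),
        index=[f"sp{i}" for i in range(5)],
        columns=["t1", "t2"],
    )
    return tc.TraitMatrix(df)
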