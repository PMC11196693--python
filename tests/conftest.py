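import numpy as np
import pandas as pd
import pytest

from stoichflex.dataset import Dataset


def build_dataset(records, covariate_names=()):
    """Dataset from a list of dicts; np_ratio filled from leaf_n/leaf_p."""
    df = pd.DataFrame(records)
    if "record_id" not in df.columns:
        df.insert(0, "record_id", [f"r{i:04d}" for i in range(len(df))])
    if "np_ratio" not in df.columns:
        df["np_ratio"] = df["leaf_n"] / df["leaf_p"]
    return Dataset(df, covariate_names=list(covariate_names))


@pytest.fixture
def toy_two_species():
    """Species A with leaf_n {1, 3}, species B with {10, 10} (grand mean 6)."""
    rows = []
    for i, (sp, site, n) in enumerate(
        [("A", "s1", 1.0), ("A", "s2", 3.0), ("B", "s1", 10.0), ("B", "s2", 10.0)]
    ):
        rows.append(
            {"species": sp, "site_id": site, "leaf_n": n, "leaf_p": 1.0}
        )
    return build_dataset(rows)


@pytest.fixture
def random_dataset():
    """100-record random positive-trait dataset with two covariates."""
    rng = np.random.default_rng(42)
    n = 100
    rows = []
    for i in range(n):
        rows.append(
            {
                "species": f"sp{rng.integers(0, 12):02d}",
                "genus": f"g{rng.integers(0, 5)}",
                "family": f"f{rng.integers(0, 3)}",
                "site_id": f"S{rng.integers(0, 15):02d}",
                "leaf_n": float(rng.lognormal(3.0, 0.4)),
                "leaf_p": float(rng.lognormal(0.4, 0.4)),
                "temp": float(rng.normal()),
                "precip": float(rng.normal()),
            }
        )
    return build_dataset(rows, covariate_names=["temp", "precip"])
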