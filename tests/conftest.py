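import numpy as np
import pandas as pd
import pytest

from comorbmap.data_model import Covariate, CovariateSchema, Dataset
from comorbmap.synthetic import SimulationConfig, lattice11_graph, simulate_dataset


@pytest.fixture(scope="session")
def lattice():
    return lattice11_graph()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=5))


def binary_schema(name="sex", levels=("male", "female"), ref="male"):
    return CovariateSchema((Covariate(name, levels, ref),))


def make_dataset(outcomes, ages=None, sex=None, regions=None, clusters=None,
                 schema=None):
    """Small single-covariate dataset for unit tests."""
    n = len(outcomes)
    schema = schema or binary_schema()
    ages = np.asarray(ages) if ages is not None else np.arange(n) % 60
    sex = sex if sex is not None else np.where(np.arange(n) % 2 == 0,
                                               "male", "female")
    regions = regions if regions is not None else ["A"] * n
    clusters = clusters if clusters is not None else ["c0"] * n
    rec = pd.DataFrame({"outcome": outcomes, "age_months": ages,
                        "region_id": regions, "cluster_id": clusters,
                        "sex": sex})
    ids = sorted(set(clusters))
    coords = pd.DataFrame({"lon": 36.0 + np.arange(len(ids)),
                           "lat": [8.0] * len(ids)},
                          index=pd.Index(ids, name="cluster_id"))
    return Dataset(records=rec, cluster_coords=coords, schema=schema)
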