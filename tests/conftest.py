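import numpy as np
import pandas as pd
import pytest

from surfnom import simulate, surfaceome


def make_counts(values, features=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                        columns=samples)


def catalog_of(cohort) -> surfaceome.SurfaceCatalog:
    return surfaceome.build_catalog(
        [surfaceome.AnnotationSource(sid, frozenset(members))
         for sid, members in cohort.annotations.items()]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the generator's reference settings."""
    return simulate.simulate_cohort(simulate.SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_catalog(default_cohort):
    return catalog_of(default_cohort)
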