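import numpy as np
import pandas as pd
import pytest

from pahmix import RunConfig, run_pipeline, toxmix
from pahmix.mixtures import ComponentSpec, MixtureDefinition


@pytest.fixture(scope="session")
def toxmix_def():
    return toxmix()


@pytest.fixture(scope="session")
def simple_mixture():
    """Two-component mixture with convenient round numbers."""
    return MixtureDefinition(
        name="demo",
        components=(
            ComponentSpec("alpha", 0.7, tef=1.0),
            ComponentSpec("beta", 0.3, tef=0.01),
        ),
        full_strength_total=10.0,
    )


@pytest.fixture(scope="session")
def additive_result():
    """Full pipeline run on noise-free additive synthetic data (uM axis).

    Session-scoped: several tests (closure, manifest structure, report
    content) read from the same run.
    """
    import warnings

    config = RunConfig(mode="simulate", noise_sd=0.0, seed=11, axes=("uM",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # noise-0 data has tied null cells
        return run_pipeline(config)


def ll4_params(b=-1.0, c=0.0, d=4.0, e=10.0):
    return {"b": b, "c": c, "d": d, "e": e}


@pytest.fixture
def ll4_exact_data():
    """Observations lying exactly on an LL.4 curve (b=-1, c=0, d=4, e=10)."""
    doses = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0])
    with np.errstate(divide="ignore"):
        y = np.where(
            doses > 0, 4.0 / (1.0 + (doses / 10.0) ** -1.0), 0.0
        )
    return doses, y
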