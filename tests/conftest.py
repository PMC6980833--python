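import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import scatdiet as sd
from scatdiet.model import PosteriorDraws

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SPECIES = ["sp1", "sp2", "sp3", "sp4", "sp5"]
START = pd.Timestamp("2017-11-03")


@pytest.fixture(scope="session")
def species():
    return list(SPECIES)


@pytest.fixture(scope="session")
def schedule(species):
    """17-day, two-individual synthetic feeding schedule."""
    return sd.generate_feeding_schedule(
        n_days=17, individuals=["A", "B"], species=species,
        max_species_per_day=3, seed=11,
    )


@pytest.fixture(scope="session")
def true_params(species):
    return sd.example_true_parameters(species, seed=12)


@pytest.fixture(scope="session")
def detections(schedule, true_params):
    scat_days = [START + pd.Timedelta(days=d) for d in range(3, 14)]
    return sd.simulate_detections(
        schedule, true_params, scat_days, degradation_days=[0, 3, 5, 12], seed=13
    )


@pytest.fixture(scope="session")
def model_input(detections, schedule):
    return sd.build_model_input(detections, schedule)


def make_draws(params: dict, n_chains: int = 1) -> PosteriorDraws:
    """Hand-built PosteriorDraws from {name: 1-D array of draws}."""
    names = list(params)
    cols = [np.asarray(params[n], dtype=float) for n in names]
    n = cols[0].shape[0]
    assert all(c.shape == (n,) for c in cols)
    draws = np.stack(cols, axis=-1)[None, :, :]
    if n_chains > 1:
        draws = np.repeat(draws, n_chains, axis=0)
    species = sorted({nm.split("[")[1][:-1] for nm in names if nm.startswith("beta0[")})
    return PosteriorDraws(
        draws=draws, names=names, n_chains=n_chains, n_iter=n,
        n_burnin=0, seed=0, species_labels=species,
    )
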