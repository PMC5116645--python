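import numpy as np
import pandas as pd
import pytest

from mrue.synth import ExperimentDesign, GeneratorParams, generate_experiment


def random_record_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random valid plot-year records: positive availabilities spanning
    several orders of magnitude, absorption fractions in (0, 1)."""
    par = np.exp(rng.uniform(2, 12, n))
    ms = np.exp(rng.uniform(2, 16, n))
    ns = np.exp(rng.uniform(0, 6, n))
    frac = rng.uniform(0.05, 0.95, (3, n))
    return pd.DataFrame(
        {
            "plot_id": [f"R{i}" for i in range(n)],
            "treatment": 0.0,
            "year": 1,
            "anpp": np.exp(rng.uniform(3, 7, n)),
            "par": par,
            "apar": frac[0] * par,
            "ms": ms,
            "tr": frac[1] * ms,
            "ns": ns,
            "n_uptake": frac[2] * ns,
        }
    )


@pytest.fixture(scope="session")
def default_records() -> pd.DataFrame:
    return generate_experiment(ExperimentDesign(seed=0), GeneratorParams())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
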