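import numpy as np
import pytest

from ease_score import (
    EchoMeasurements,
    GeneratorParams,
    default_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def big_cohort():
    """Default-parameter cohort, n=10^4, fixed seed; shared across tests."""
    return generate_cohort(GeneratorParams(n=10_000, seed=42))


@pytest.fixture(scope="session")
def cohort_5k():
    return generate_cohort(GeneratorParams(n=5_000, seed=42))


def random_measurements(rng: np.random.Generator) -> EchoMeasurements:
    """A random but physiologically plausible measurement vector."""
    return EchoMeasurements(
        lasr_pct=rng.uniform(3.0, 45.0),
        pa_tdi_ms=rng.uniform(60.0, 220.0),
        lavi_ml_m2=rng.uniform(15.0, 75.0),
        e_over_eprime=rng.uniform(3.0, 25.0),
        lasct_pct=rng.uniform(1.0, 20.0),
    )
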