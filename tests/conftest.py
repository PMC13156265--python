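import numpy as np
import pandas as pd
import pytest

import pulmoref as pr


@pytest.fixture(scope="session")
def models():
    """The four bundled reference models."""
    return pr.default_models()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-sized (182 animal) synthetic cohort, fixed seed."""
    return pr.generate_cohort(pr.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def balanced_animals():
    """2000 animals, balanced strain/sex, masses uniform over 160-750 g."""
    rng = np.random.default_rng(99)
    n = 2000
    return pd.DataFrame(
        {
            "animal_id": [f"a{i:04d}" for i in range(n)],
            "strain": np.tile(["sprague_dawley", "wistar"], n // 2),
            "sex": np.repeat(np.tile(["female", "male"], n // 4), 2),
            "mass_g": rng.uniform(160.0, 750.0, n),
        }
    )
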