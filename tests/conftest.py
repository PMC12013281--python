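import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from srtddm.cohort import preset_scenarios, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture(scope="session")
def small_cohort():
    """Two presets x 4 participants, shared across behavioural tests."""
    scenarios = preset_scenarios(n_participants=4)
    return simulate_cohort(
        [scenarios["probabilistic-concealed"], scenarios["mixed-concealed"]], 1234
    )
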