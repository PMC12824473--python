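import numpy as np
import pandas as pd
import pytest

from yprofiler import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-line, 200-gene cohort with 5 planted genes, fixed seed."""
    return synthetic.simulate_cohort(n_lines=10, n_genes=200, planted=5, effect=2.0, seed=11)


@pytest.fixture(scope="session")
def signature_fixture():
    """Noisy 3-class signature profiles plus matching GMT dict and labels."""
    return synthetic.simulate_signature_profiles(
        ["alpha", "beta", "gamma"], markers_per_class=20, n_samples_per_class=4,
        noise_sd=0.5, seed=5,
    )


@pytest.fixture
def tidy_viability():
    """Hand-built raw viability table: 2 lines x 2 replicates x 3 activities."""
    rows = []
    for line, scale in [("L1", 2.0), ("L2", 4.0)]:
        for rep in (1, 2):
            for act, frac in [(0.0, 1.0), (10.0, 0.5), (20.0, 0.25)]:
                rows.append(
                    {
                        "cell_line": line,
                        "replicate": rep,
                        "activity_mbq_per_ml": act,
                        "readout": scale * frac,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
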