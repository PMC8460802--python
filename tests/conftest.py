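import numpy as np
import pandas as pd
import pytest

import cyclemark as cm


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene simulation with Pol II + H3K4me3 reads; shared read-only."""
    return cm.simulate_dataset(n_genes=300, seed=42, reads_per_gene=80,
                               antibodies=("polII", "H3K4me3"))


@pytest.fixture(scope="session")
def default_design():
    return cm.TimeCourseDesign()


@pytest.fixture(scope="session")
def toy_counts():
    """Deterministic small count matrix on a 2x3 design."""
    design = cm.TimeCourseDesign(time_points_hours=(0, 3, 6))
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(50, size=(20, 6)) + 1,
        index=[f"g{i}" for i in range(20)], columns=design.sample_ids)
    return design, counts
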