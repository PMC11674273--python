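import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rthclat import CountMatrix, datasets

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def screening_triplicates():
    """HMOX1/JUN qPCR triplicates for the 28 screening-panel chemicals."""
    return datasets.load_screening_foldchanges()


@pytest.fixture(scope="session")
def screening_printed():
    return datasets.load_screening_printed().set_index("chemical")


@pytest.fixture(scope="session")
def screening_llna():
    return datasets.llna_lookup("screening")


@pytest.fixture(scope="session")
def concordance_panel():
    """9 reference chemicals x 12 candidate genes with printed verdicts."""
    return datasets.load_concordance_panel()


@pytest.fixture()
def toy_counts():
    """6 genes x 6 samples, two groups, hand-sized for exact assertions."""
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(6)]
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(6, 6)), index=genes, columns=samples
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0, 1500.0, 800.0, 1200.0], index=genes)
    groups = {s: ("sensitizer" if i < 3 else "control") for i, s in enumerate(samples)}
    return CountMatrix(counts, lengths, groups)
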