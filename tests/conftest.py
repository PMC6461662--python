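import dataclasses

import numpy as np
import pytest

import ssnhist as sh
from ssnhist.pipeline import compute_fpc_features


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (56 T1 + 53 T2), fixed seed."""
    return sh.generate_cohort(dataclasses.replace(sh.GeneratorConfig(), seed=3))


@pytest.fixture(scope="session")
def fpc_artifacts(default_cohort):
    """Feature table with fpc columns, the FPCA model and the LQD curves."""
    return compute_fpc_features(default_cohort)


@pytest.fixture(scope="session")
def feature_table(fpc_artifacts):
    return fpc_artifacts[0]


@pytest.fixture(scope="session")
def fpca_model(fpc_artifacts):
    return fpc_artifacts[1]


@pytest.fixture(scope="session")
def lqd_curves(fpc_artifacts):
    return fpc_artifacts[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_histogram(center_counts: dict[float, int], spacing: float = 100.0):
    """Histogram from a sparse {bin_center: count} dict on a uniform grid."""
    lo = min(center_counts)
    hi = max(center_counts)
    n = int(round((hi - lo) / spacing)) + 1
    centers = lo + spacing * np.arange(n)
    counts = np.zeros(n, dtype=int)
    for c, k in center_counts.items():
        counts[int(round((c - lo) / spacing))] = k
    return sh.AttenuationHistogram(centers, counts)
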