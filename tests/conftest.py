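import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from pirads3.preprocess import QuantizedROI
from pirads3.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def study():
    """One deterministic synthetic lesion study (csPCa positive)."""
    spec = CohortSpec(seed=5, n_patients=2, n_positive=1)
    cohort = generate_cohort(spec)
    return next(s for s in cohort if s.clinical.label == 1)


@pytest.fixture(scope="session")
def small_cohort():
    """A 15-patient cohort small enough for end-to-end pipeline tests."""
    return generate_cohort(CohortSpec(seed=7, n_patients=15, n_positive=5))


def random_quantized_roi(rng, shape=(3, 5, 5), n_levels=4, mask_fill=0.8):
    """Random small labelled ROI for oracle-equivalence checks."""
    mask = rng.random(shape) < mask_fill
    if not mask.any():
        mask[tuple(d // 2 for d in shape)] = True
    labels = np.zeros(shape, dtype=np.int32)
    labels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return QuantizedROI(
        labels=labels,
        mask=mask,
        n_bins=n_levels,
        bin_edges=np.linspace(0, 1, n_levels + 1),
        spacing=(1.0, 1.0, 1.0),
    )
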