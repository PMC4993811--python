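import numpy as np
import pytest

from braincohort.spaces import AffineTransform
from braincohort.synth import CohortConfig, generate_cohort


def random_affine(rng, max_scale=2.0):
    """A random well-conditioned affine (rotation x scale x translation)."""
    # QR of a random matrix gives a rotation; diagonal scales keep it
    # well-conditioned
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    scales = rng.uniform(0.5, max_scale, size=3)
    m = np.eye(4)
    m[:3, :3] = q * scales
    m[:3, 3] = rng.uniform(-20, 20, size=3)
    return AffineTransform(m)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small on-disk synthetic project (3 groups x 2 subjects)."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(
        seed=7,
        groups=(("term", 2), ("preterm_control", 2), ("preterm_kmc", 2)),
        bundle_counts={"term": 12, "preterm_control": 9, "preterm_kmc": 10},
        n_outliers=1,
    )
    layout, manifest = generate_cohort(cfg, str(out))
    return cfg, layout, manifest


@pytest.fixture(scope="session")
def study_cohort_subjects():
    """The full default study conditions, in memory (3 x 20 subjects)."""
    from braincohort.synth import simulate_cohort

    cfg = CohortConfig(seed=11)
    return cfg, simulate_cohort(cfg)
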