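import numpy as np
import pytest

from mdmgroup import (
    GroupStudy,
    PriorPolicy,
    SubjectSeries,
    simulate_group,
)
from mdmgroup.simulate import CoefficientProcess, _preset


@pytest.fixture(scope="session")
def fast_policy() -> PriorPolicy:
    """Single-discount policy: static-coefficient scoring, fast."""
    return PriorPolicy(delta_grid=(1.0,))


@pytest.fixture(scope="session")
def tiny_bundle():
    """3 subgroups x 2 subjects, 4 nodes, short series; constant coefficients
    (the tie-heavy worst case for score equivalence)."""
    spec = _preset(
        1, n=4, T=120, n_groups=3, subjects_per_group=2,
        process=CoefficientProcess(), n_mutations=2, min_shd=2, max_in_degree=2,
    )
    return simulate_group(spec)


@pytest.fixture(scope="session")
def tiny_study(tiny_bundle, fast_policy) -> GroupStudy:
    study = GroupStudy.from_bundle(tiny_bundle, policy=fast_policy, max_parents=2)
    study.ensure_tables()
    return study


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_series(values, subject_id="s", names=None) -> SubjectSeries:
    values = np.asarray(values, dtype=float)
    names = names or tuple(f"R{j+1}" for j in range(values.shape[1]))
    return SubjectSeries(subject_id=subject_id, values=values, region_names=names)
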