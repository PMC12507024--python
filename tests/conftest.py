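import numpy as np
import pytest

from syncom_select.profiles import PfamProfile, ProfileMatrix, build_profile_matrix


def pf(n: int) -> str:
    """Shorthand: pf(1) -> 'PF00001'."""
    return f"PF{n:05d}"


def profile(entity_id: str, *nums: int) -> PfamProfile:
    return PfamProfile(entity_id=entity_id, pfams=frozenset(pf(n) for n in nums))


@pytest.fixture
def two_by_three() -> ProfileMatrix:
    """The hand-laid-out 2x3 matrix: rows [1,1,0] and [0,1,1] over PF00001..3."""
    return build_profile_matrix([profile("e1", 1, 2), profile("e2", 2, 3)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_profile(rng: np.random.Generator, entity_id: str, universe: int = 30) -> PfamProfile:
    k = int(rng.integers(0, universe + 1))
    nums = rng.choice(universe, size=k, replace=False) + 1
    return profile(entity_id, *nums.tolist())
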