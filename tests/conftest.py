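import numpy as np
import pytest

from matchtrend import MatchedSet, MatchedStudy, load_access


@pytest.fixture(scope="session")
def access():
    return load_access()


def make_random_study(
    rng: np.random.Generator, n_sets: int = 30, m: int = 2, n_strata: int = 2
) -> MatchedStudy:
    """A small random matched study with all three genotypes represented."""
    while True:
        sets = []
        for i in range(n_sets):
            lab = f"S{rng.integers(n_strata) + 1}"
            case = int(rng.integers(3))
            ctrls = tuple(int(g) for g in rng.integers(0, 3, size=m))
            sets.append(MatchedSet(lab, case, ctrls))
        study = MatchedStudy(tuple(sets))
        genos = [s.case for s in study.sets] + [g for s in study.sets for g in s.controls]
        if len(set(genos)) == 3 and len(study.strata) == n_strata:
            return study


@pytest.fixture
def random_study():
    return make_random_study(np.random.default_rng(42))
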