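import numpy as np
import pytest

from healthrank import (
    CriterionSpec,
    DecisionMatrix,
    Direction,
    compute_weights,
    oecd_fixture,
)

# Scores/ranks published for the OECD fixture, used as frozen expectations
# across the suite (9-decimal display precision of the source tables).
PUBLISHED_WEIGHTS = {
    "C1": 0.16399,
    "C2": 0.22255,
    "C3": 0.162676,
    "C4": 0.134833,
    "C5": 0.160519,
    "C6": 0.155432,
}
PUBLISHED_MAIRCA = {
    "Australia": (0.007816978, 5),
    "Austria": (0.008806488, 9),
    "Belgium": (0.010257712, 12),
    "Canada": (0.011008578, 13),
    "Chile": (0.018020733, 20),
    "Costa Rica": (0.023625604, 24),
    "Czechia": (0.014434814, 18),
    "Denmark": (0.007452328, 4),
    "Germany": (0.010045510, 11),
    "Greece": (0.013332668, 17),
    "Hungary": (0.022538774, 23),
    "Israel": (0.008597807, 6),
    "Italy": (0.009235821, 10),
    "Japan": (0.007451768, 3),
    "Korea": (0.011163273, 14),
    "Latvia": (0.026233206, 26),
    "Mexico": (0.033711558, 27),
    "Netherlands": (0.008735633, 7),
    "Poland": (0.018940257, 22),
    "Portugal": (0.012776727, 16),
    "Slovak Republic": (0.018344506, 21),
    "Slovenia": (0.012140059, 15),
    "Spain": (0.008754547, 8),
    "Sweden": (0.006806885, 2),
    "Switzerland": (0.002907196, 1),
    "Türkiye": (0.024165697, 25),
    "United States": (0.015581021, 19),
}
PUBLISHED_MARCOS = {
    "Australia": (0.551572645, 10),
    "Austria": (0.572495183, 6),
    "Belgium": (0.507832173, 12),
    "Canada": (0.484977857, 16),
    "Chile": (0.344133010, 23),
    "Costa Rica": (0.300322345, 25),
    "Czechia": (0.465455766, 17),
    "Denmark": (0.669277009, 2),
    "Germany": (0.526209409, 11),
    "Greece": (0.446566390, 19),
    "Hungary": (0.332206408, 24),
    "Israel": (0.651894844, 3),
    "Italy": (0.557500453, 9),
    "Japan": (0.608313386, 5),
    "Korea": (0.502109836, 13),
    "Latvia": (0.362068924, 22),
    "Mexico": (0.245292106, 27),
    "Netherlands": (0.562207960, 8),
    "Poland": (0.407213407, 20),
    "Portugal": (0.462552104, 18),
    "Slovak Republic": (0.396362923, 21),
    "Slovenia": (0.490098793, 15),
    "Spain": (0.568238873, 7),
    "Sweden": (0.61407414, 4),
    "Switzerland": (0.776970011, 1),
    "Türkiye": (0.291241613, 26),
    "United States": (0.499402269, 14),
}


@pytest.fixture(scope="session")
def oecd():
    return oecd_fixture()


@pytest.fixture(scope="session")
def oecd_weights(oecd):
    weights, _ = compute_weights(oecd)
    return weights


@pytest.fixture
def random_matrix_factory():
    """Factory of random positive decision matrices with mixed directions."""

    def make(seed, m=10, n=4):
        rng = np.random.default_rng(seed)
        values = rng.uniform(1.0, 100.0, size=(m, n))
        directions = [
            Direction.BENEFIT if rng.random() < 0.5 else Direction.COST
            for _ in range(n)
        ]
        criteria = [
            CriterionSpec(f"C{j+1}", d) for j, d in enumerate(directions)
        ]
        return DecisionMatrix([f"A{i}" for i in range(m)], criteria, values)

    return make
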