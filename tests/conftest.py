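import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wormchoice.core import BudgetSpec
from wormchoice.garp import PriceQuantityDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20230425)


def random_line_dataset(rng, K: int, density_range=(0.1, 10.0)) -> PriceQuantityDataset:
    """Uniform bundles on K random two-good budget lines (own expenditure 1)."""
    lo, hi = np.log10(density_range[0]), np.log10(density_range[1])
    d = 10.0 ** rng.uniform(lo, hi, size=(K, 2))
    shares = rng.uniform(0.0, 1.0, size=K)
    prices = 1.0 / d
    bundles = np.column_stack([shares * d[:, 0], (1.0 - shares) * d[:, 1]])
    return PriceQuantityDataset(prices, bundles)


@pytest.fixture
def mutual_strict_dataset():
    """Hand-constructed two-budget dataset with two direct violations.

    Prices (1,2)/(2,1), choices (2,3)/(3,2): each bundle costs 8 on its own
    budget and 7 at the other's prices, so each choice is strictly revealed
    preferred to the other.
    """
    return PriceQuantityDataset(prices=[[1, 2], [2, 1]], bundles=[[2, 3], [3, 2]])


@pytest.fixture
def no_cross_dataset():
    """Same prices, choices (6,1)/(1,6): each costs 13 at the other's prices
    against an own expenditure of 8, so no cross relations exist."""
    return PriceQuantityDataset(prices=[[1, 2], [2, 1]], bundles=[[6, 1], [1, 6]])


@pytest.fixture
def seven_budget_ensemble():
    from wormchoice.synth import default_worm_ensemble

    return default_worm_ensemble()


def make_ensemble(rng, K: int, ratio_span=(-2.0, 2.0)) -> list:
    ratios = np.sort(rng.uniform(*ratio_span, size=K))
    anchor = 10.0 ** rng.uniform(-0.3, 0.3)
    return [
        BudgetSpec(f"b{i}", anchor * 10 ** (r / 2), anchor * 10 ** (-r / 2))
        for i, r in enumerate(ratios)
    ]
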