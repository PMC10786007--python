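import warnings

import pytest

from namerel.synthetic_data import GenerativeParams, simulate_dataset
from namerel.trial_data import filter_trials

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small two-session cohort (15 participants x 20 items), fixed seed."""
    params = GenerativeParams(n_participants=15, n_items=20, seed=42)
    trials, truth = simulate_dataset(params)
    return params, trials, truth


@pytest.fixture(scope="session")
def tiny_correct(tiny_dataset):
    _, trials, _ = tiny_dataset
    correct, report = filter_trials(trials)
    return correct, report


@pytest.fixture(scope="session")
def study_dataset():
    """One cohort at the full study design size (50 x 150 x 2 sessions)."""
    params = GenerativeParams(seed=314)
    trials, truth = simulate_dataset(params)
    return params, trials, truth
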