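import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from usvmeal.core import BehaviorScan, Session, UsvEvent
from usvmeal.synthdata import SyntheticScenario


@pytest.fixture(scope="session")
def null_scenario() -> SyntheticScenario:
    """No behaviour-subtype association: the shuffling test's null."""
    return SyntheticScenario(n_rats=4, phase_duration_s=600, seed=11,
                             association_strength=0.0)


@pytest.fixture(scope="session")
def assoc_scenario() -> SyntheticScenario:
    """Full behaviour-specific subtype mixtures (planted associations)."""
    return SyntheticScenario(n_rats=4, phase_duration_s=600, seed=11,
                             association_strength=1.0)


@pytest.fixture()
def hand_session() -> Session:
    """Five events over a hand-built scan, for exhaustive manual tallies.

    Scan (10 bins): Feeding x4, Grooming x3, Immobile x3.
    Events: flats at 0.5 s and 3.9 s (Feeding), trill at 4.2 s (Grooming),
    flat at 7.0 s (Immobile), short at 9.9 s (Immobile).
    """
    scan = BehaviorScan(
        session_id="r1-consumption",
        phase="consumption",
        labels=["Feeding"] * 4 + ["Grooming"] * 3 + ["Immobile"] * 3,
    )
    mk = lambda t, st: UsvEvent(
        "r1-consumption", t, t + 0.05, subtype=st, median_freq_khz=40.0
    )
    events = [
        mk(0.5, "flat"),
        mk(3.9, "flat"),
        mk(4.2, "trill"),
        mk(7.0, "flat"),
        mk(9.9, "short"),
    ]
    return Session(
        session_id="r1-consumption", rat_id="r1", phase="consumption",
        events=events, scan=scan,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
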