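import logging

import pytest

from sociospatial.survey import Gazetteer, Participant, Place, WellBeingScores

logging.disable(logging.WARNING)


@pytest.fixture
def small_gazetteer():
    """Three churches at 5, 12 and 30 km east of the origin plus a shop."""
    return Gazetteer(
        [
            Place("church-a", "church", (5_000.0, 0.0)),
            Place("church-b", "church", (12_000.0, 0.0)),
            Place("church-c", "church", (30_000.0, 0.0)),
            Place("shop-a", "shop", (1_000.0, 2_000.0)),
        ]
    )


def make_participant(pid="P1", community="C1", home=(0.0, 0.0), mcs=50.0, pcs=50.0, isolation=50.0):
    return Participant(
        id=pid,
        community=community,
        home=home,
        scores=WellBeingScores(mcs=mcs, pcs=pcs, isolation=isolation),
    )


@pytest.fixture
def participant_factory():
    return make_participant
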