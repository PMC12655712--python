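import numpy as np
import pandas as pd
import pytest

from milksupply.growth import GrowthReference
from milksupply.measures import FeedDiary, FeedEvent, FeedKind


@pytest.fixture(scope="session")
def ref():
    return GrowthReference.bundled()


@pytest.fixture(scope="session")
def flat_ref():
    """A tiny analytic reference grid with constant L, M, S (easy closed
    forms): L=1 makes z = (W/M - 1)/S."""
    rows = []
    for sex in ("male", "female"):
        for age in (0, 50, 100, 150, 200):
            rows.append({"sex": sex, "age_days": age, "L": 1.0,
                         "M": 5000.0, "S": 0.1})
    return GrowthReference(pd.DataFrame(rows))


def breastfeed(end_h, vol_ml, start_offset_min=15.0, base=5000.0):
    """A breastfeed event ending at ``end_h`` hours transferring vol_ml."""
    end = end_h * 60.0
    return FeedEvent(end - start_offset_min, end, FeedKind.BREASTFEED,
                     base, base + vol_ml * 1.03)


def diary_from_feeds(spec, dyad_id="T0"):
    """Diary from a list of (end_hour, volume_ml) breastfeeds."""
    return FeedDiary(dyad_id, [breastfeed(h, v) for h, v in spec])


@pytest.fixture
def simple_diary():
    """The worked example: feeds ending at hours 0..24.5."""
    return diary_from_feeds(
        [(0, 60), (4, 80), (9, 70), (15, 90), (20, 60), (24.5, 85)]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One default synthetic cohort with derived measures (seed-fixed)."""
    import milksupply as ms

    cohort, diaries, truth = ms.generate_cohort(seed=7)
    derived = ms.derive_measures(cohort, diaries, GrowthReference.bundled())
    return derived, truth
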