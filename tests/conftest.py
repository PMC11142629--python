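import numpy as np
import pytest

from tcnet.covariates import HistoryIndex, WindowConfig
from tcnet.event_data import ResidentRecord, build_presence_grid

from oracles import STAFF, Ev


def make_roster(n, horizon, rng=None, staggered=True):
    """A small roster with mildly varied attributes and entry days."""
    rng = rng or np.random.default_rng(0)
    roster = []
    for k in range(n):
        entry = int(rng.integers(0, max(1, horizon // 3))) if staggered else 0
        roster.append(
            ResidentRecord(
                id=f"r{k:02d}",
                entry_day=entry,
                exit_day=horizon,
                age=float(20 + rng.integers(0, 30)),
                race_white=bool(rng.random() < 0.8),
                lsir=float(13 + rng.integers(0, 28)),
            )
        )
    return roster


def index_from_events(events, n_residents, window):
    h = HistoryIndex(n_residents, window)
    for e in sorted(events, key=lambda e: e.day):
        h.record(e.day, e.s, e.r, e.net, e.ht)
    return h


@pytest.fixture
def small_roster():
    return make_roster(6, 60, staggered=False)


@pytest.fixture
def small_grid(small_roster):
    return build_presence_grid(small_roster, 60)


@pytest.fixture
def default_window():
    return WindowConfig()
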