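import datetime as dt
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pridenet.observations import GroupScan, Individual, InteractionEvent
from pridenet.synth import ngamo_like_config, simulate_pride


def make_individual(id_, sex="female", age_class="adult", **kw):
    return Individual(id=id_, sex=sex, age_class=age_class, **kw)


@pytest.fixture(scope="session")
def ngamo_small():
    """A short (40-day) simulated campaign of the 12-lion reference pride."""
    cfg = ngamo_like_config(n_days=40, seed=11)
    return simulate_pride(cfg)


@pytest.fixture
def toy_roster():
    return tuple(make_individual(i) for i in ("A", "B", "C", "D"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_scans(rng, ids, n_scans):
    """Random present/absent splits over the roster (some ids unobserved)."""
    scans = []
    t0 = dt.datetime(2012, 1, 6, 7, 0)
    for k in range(n_scans):
        mask = rng.random(len(ids)) < rng.uniform(0.2, 0.9)
        present = frozenset(i for i, m in zip(ids, mask) if m)
        if not present:
            present = frozenset([ids[int(rng.integers(len(ids)))]])
        scans.append(
            GroupScan(
                session_id=f"s{k}",
                timestamp=t0 + dt.timedelta(hours=k),
                present=present,
                absent=frozenset(ids) - present,
            )
        )
    return scans


def random_events(rng, ids, n_events, behaviors=("play", "greeting", "social_licking")):
    t0 = dt.datetime(2012, 1, 6, 7, 0)
    events = []
    for _ in range(n_events):
        i, j = rng.choice(len(ids), size=2, replace=False)
        events.append(
            InteractionEvent(
                timestamp=t0 + dt.timedelta(seconds=float(rng.uniform(0, 3600 * 24))),
                initiator=ids[int(i)],
                recipient=ids[int(j)],
                behavior=str(rng.choice(behaviors)),
            )
        )
    return events


def random_digraph(rng, n, density=0.5, weighted=True):
    v = (rng.random((n, n)) < density).astype(float)
    if weighted:
        v *= rng.integers(1, 9, size=(n, n))
    np.fill_diagonal(v, 0.0)
    return v
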