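"""Event logs, rosters, and the dyad-day observation grid.

A therapeutic-community (TC) unit produces two longitudinal directed
networks: written *affirmations* (rewarding prosocial behaviour) and
written *corrections* (sanctioning norm violations).  Each record names a
sender, a receiver, the calendar day (integer days since the start of
observation), the network, whether a correction sanctioned "head-turning"
(ignoring a peer behaviour that should have been corrected), and whether
the sender was a staff member.

Residents enter and leave the unit; the *presence grid* records who is in
the unit on each day and thereby defines the dyadic risk set: ties are
defined only for ordered pairs of residents co-present on a day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AFFIRMATION = "affirmation"
CORRECTION = "correction"
NETWORKS = (AFFIRMATION, CORRECTION)

EVENT_COLUMNS = ["sender", "receiver", "day", "network", "headturn", "staff_sender"]
ROSTER_COLUMNS = ["id", "entry_day", "exit_day", "age", "race_white", "lsir"]

LSIR_MIN, LSIR_MAX = 0, 54  # instrument range of the LSI-R risk score


class ValidationError(ValueError):
    """Raised when an event log or roster violates a structural invariant."""


@dataclass(frozen=True)
class EventRecord:
    """One dated, directed affirmation or correction."""

    sender_id: str
    receiver_id: str
    day: int
    network: str
    headturn: bool = False
    staff_sender: bool = False

    def validate(self) -> None:
        if self.network not in NETWORKS:
            raise ValidationError(f"unknown network {self.network!r}")
        if self.day < 0:
            raise ValidationError(f"negative day {self.day}")
        if self.headturn and self.network != CORRECTION:
            raise ValidationError("head-turn flag is only meaningful on corrections")
        if not self.staff_sender and self.sender_id == self.receiver_id:
            raise ValidationError(f"self-loop on resident {self.sender_id!r}")


@dataclass(frozen=True)
class ResidentRecord:
    """Roster entry: presence interval [entry_day, exit_day) plus attributes."""

    id: str
    entry_day: int
    exit_day: int
    age: float
    race_white: bool
    lsir: float

    def validate(self) -> None:
        if self.entry_day >= self.exit_day:
            raise ValidationError(
                f"resident {self.id!r}: entry_day {self.entry_day} >= exit_day {self.exit_day}"
            )
        if not (LSIR_MIN <= self.lsir <= LSIR_MAX):
            raise ValidationError(
                f"resident {self.id!r}: LSI-R {self.lsir} outside [{LSIR_MIN}, {LSIR_MAX}]"
            )


class PresenceGrid:
    """Who is in the unit on each day; defines the dyadic risk set.

    Residents are indexed 0..n-1 in roster order; ``ids`` maps index to
    identifier.  ``present(r, t)`` is true iff entry_day(r) <= t < exit_day(r)
    (exit truncated at the horizon).
    """

    def __init__(self, roster: Sequence[ResidentRecord], horizon: int):
        self.roster = list(roster)
        self.horizon = int(horizon)
        self.ids = [r.id for r in self.roster]
        self.index = {rid: k for k, rid in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise ValidationError("duplicate resident ids in roster")
        self.entry = np.array([r.entry_day for r in self.roster], dtype=int)
        self.exit = np.array([r.exit_day for r in self.roster], dtype=int)
        self._exit_trunc = np.minimum(self.exit, self.horizon)

    @property
    def n_residents(self) -> int:
        return len(self.roster)

    def present(self, resident, day: int) -> bool:
        k = resident if isinstance(resident, (int, np.integer)) else self.index[resident]
        return bool(self.entry[k] <= day < self._exit_trunc[k])

    def present_idx(self, day: int) -> np.ndarray:
        """Indices of residents present on ``day``."""
        return np.flatnonzero((self.entry <= day) & (day < self._exit_trunc))

    def headcounts(self) -> np.ndarray:
        days = np.arange(self.horizon)
        return (
            (self.entry[:, None] <= days[None, :]) & (days[None, :] < self._exit_trunc[:, None])
        ).sum(axis=0)

    def resident_days(self) -> int:
        return int(np.maximum(self._exit_trunc - np.minimum(self.entry, self._exit_trunc), 0).sum())


def build_presence_grid(
    roster: Sequence[ResidentRecord],
    horizon: int,
    capacity: int | None = None,
    truncate: bool = False,
) -> PresenceGrid:
    """Build the day-by-day presence grid for a roster.

    ``horizon`` must cover every exit day unless ``truncate`` is set, in which
    case stays running past the horizon are clipped.  If ``capacity`` is given,
    a head-count exceeding it raises a warning (never an error: real logs can
    contain transfer-day overlaps).
    """
    for r in roster:
        r.validate()
    if horizon < 1:
        raise ValidationError("horizon must be at least one day")
    max_exit = max((r.exit_day for r in roster), default=0)
    if max_exit > horizon and not truncate:
        raise ValidationError(
            f"horizon {horizon} < max exit day {max_exit}; pass truncate=True to clip"
        )
    grid = PresenceGrid(roster, horizon)
    if capacity is not None:
        peak = int(grid.headcounts().max(initial=0))
        if peak > capacity:
            warnings.warn(
                f"peak head-count {peak} exceeds bed capacity {capacity}", stacklevel=2
            )
    return grid


def _as_bool(x, row: int, col: str) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"0", "false"}:
        return False
    if s in {"1", "true"}:
        return True
    raise ValidationError(f"row {row}: column {col!r} has non-boolean value {x!r}")


def load_roster(path) -> list[ResidentRecord]:
    df = pd.read_csv(path)
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"roster missing columns {missing}")
    roster = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        r = ResidentRecord(
            id=str(rec.id),
            entry_day=int(rec.entry_day),
            exit_day=int(rec.exit_day),
            age=float(rec.age),
            race_white=_as_bool(rec.race_white, row, "race_white"),
            lsir=float(rec.lsir),
        )
        try:
            r.validate()
        except ValidationError as e:
            raise ValidationError(f"roster row {row}: {e}") from None
        roster.append(r)
    return roster


def write_roster(roster: Sequence[ResidentRecord], path) -> None:
    pd.DataFrame(
        [
            (r.id, r.entry_day, r.exit_day, r.age, int(r.race_white), r.lsir)
            for r in roster
        ],
        columns=ROSTER_COLUMNS,
    ).to_csv(path, index=False)


def load_event_log(path, roster: Sequence[ResidentRecord]) -> list[EventRecord]:
    """Parse and validate an event log CSV against a roster.

    Validation is fatal with the offending file row number: unknown resident
    ids, head-turn flags on affirmations, resident self-loops, and events
    dated outside the sender's or receiver's presence interval.
    Records are returned sorted by day (stable).
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"event log missing columns {missing}")
    by_id = {r.id: r for r in roster}
    events: list[EventRecord] = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        ev = EventRecord(
            sender_id=str(rec.sender),
            receiver_id=str(rec.receiver),
            day=int(rec.day),
            network=str(rec.network),
            headturn=_as_bool(rec.headturn, row, "headturn"),
            staff_sender=_as_bool(rec.staff_sender, row, "staff_sender"),
        )
        try:
            ev.validate()
        except ValidationError as e:
            raise ValidationError(f"row {row}: {e}") from None
        if ev.receiver_id not in by_id:
            raise ValidationError(f"row {row}: unknown receiver id {ev.receiver_id!r}")
        if not ev.staff_sender and ev.sender_id not in by_id:
            raise ValidationError(f"row {row}: unknown sender id {ev.sender_id!r}")
        recv = by_id[ev.receiver_id]
        if not (recv.entry_day <= ev.day < recv.exit_day):
            raise ValidationError(
                f"row {row}: day {ev.day} outside receiver {ev.receiver_id!r} presence"
            )
        if not ev.staff_sender:
            snd = by_id[ev.sender_id]
            if not (snd.entry_day <= ev.day < snd.exit_day):
                raise ValidationError(
                    f"row {row}: day {ev.day} outside sender {ev.sender_id!r} presence"
                )
        events.append(ev)
    events.sort(key=lambda e: e.day)
    return events


def write_event_log(events: Iterable[EventRecord], path) -> None:
    pd.DataFrame(
        [
            (e.sender_id, e.receiver_id, e.day, e.network, int(e.headturn), int(e.staff_sender))
            for e in events
        ],
        columns=EVENT_COLUMNS,
    ).to_csv(path, index=False)


def build_outcome_grid(events: Sequence[EventRecord], grid: PresenceGrid) -> pd.DataFrame:
    """Binary tie outcomes on the dyad-day risk set, per network.

    One row per (ordered co-present resident dyad, day, network).  Multiple
    same-day events on one dyad-network collapse to a single ``tie = True``
    (the dependent variable is tie presence, not an event count).  Staff-sent
    events never create outcome rows.
    """
    tied: dict[int, set[tuple[int, int, int]]] = {}
    for e in events:
        if e.staff_sender:
            continue
        s = grid.index[e.sender_id]
        r = grid.index[e.receiver_id]
        k = NETWORKS.index(e.network)
        tied.setdefault(e.day, set()).add((s, r, k))
    senders, receivers, days, nets, ties = [], [], [], [], []
    for t in range(grid.horizon):
        present = grid.present_idx(t)
        n = len(present)
        if n < 2:
            continue
        day_ties = tied.get(t, set())
        for k, net in enumerate(NETWORKS):
            for i in present:
                for j in present:
                    if i == j:
                        continue
                    senders.append(grid.ids[i])
                    receivers.append(grid.ids[j])
                    days.append(t)
                    nets.append(net)
                    ties.append((i, j, k) in day_ties)
    return pd.DataFrame(
        {"sender": senders, "receiver": receivers, "day": days, "network": nets, "tie": ties}
    )
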