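"""Temporal-network covariates for dyad-day tie regressions.

Every predictor of the tie models is a deterministic function of (a) the
event history *strictly before* the observation day and (b) the roster.
History terms are evaluated over a sliding recency window (default: the
single preceding day), except out-isolation, which is cumulative ("has
not sent an affirmation at all").  Attribute and tenure terms come from the roster
alone.

The ``HistoryIndex`` maintains windowed aggregates incrementally so that a
whole unit-day of dyads is vectorised; scalar per-dyad accessors
(``dyadic_stats`` and friends) expose the same quantities one observation
at a time.

Coding conventions
------------------
* History terms are binary indicators by default (``use_counts`` switches
  to windowed counts; triadic counts count distinct intermediaries).
* Indegree/outdegree terms exclude the focal partner's events, so
  reciprocity and same-peer concentration capture the dyadic channel
  separately.  Staff-sourced receipts count in both the base indegree term
  and the staff term, so staff coefficients read as staff-vs-peer
  differences.
* Age and LSI-R activity/popularity are mean-centred over the full
  roster; similarity terms are range-normalised to [0, 1]; admission-time
  homophily decays linearly to 0 over ``admission_sim_scale`` days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .event_data import (
    AFFIRMATION,
    CORRECTION,
    NETWORKS,
    EventRecord,
    PresenceGrid,
    ResidentRecord,
    ValidationError,
)

_STAFF = -1  # sender code for staff events inside the index

#: Fixed predictor order of the two tie models (both models share all columns).
COVARIATE_NAMES = [
    "intercept",
    "aff_reciprocity",
    "aff_transitive_closure",
    "aff_three_cycle",
    "aff_indegree_activity",
    "aff_indegree_popularity",
    "aff_outdegree_activity",
    "aff_out_isolation_activity",
    "aff_same_peer",
    "cor_reciprocity",
    "cor_transitive_closure",
    "cor_three_cycle",
    "cor_indegree_activity",
    "cor_indegree_popularity",
    "cor_outdegree_activity",
    "cor_out_isolation_activity",
    "cor_same_peer",
    "young_activity",
    "young_popularity",
    "senior_activity",
    "senior_popularity",
    "admission_homophily",
    "white_activity",
    "white_popularity",
    "race_homophily",
    "age_activity",
    "age_popularity",
    "age_homophily",
    "lsir_activity",
    "lsir_popularity",
    "lsir_similarity",
    "staff_aff_indegree_activity",
    "staff_aff_indegree_popularity",
    "staff_cor_indegree_activity",
    "staff_cor_indegree_popularity",
    "unit_ht",
    "unit_staff_ht",
    "ht_indegree_activity",
    "staff_ht_indegree_activity",
    "ht_outdegree_popularity",
    "ht_reciprocity",
]

#: Human-readable report labels, in the same order.
REPORT_LABELS = {
    "intercept": "Intercept",
    "aff_reciprocity": "Affirmation reciprocity",
    "aff_transitive_closure": "Affirmation transitive closure",
    "aff_three_cycle": "Affirmation three cycle",
    "aff_indegree_activity": "Affirmation indegree activity",
    "aff_indegree_popularity": "Affirmation indegree popularity",
    "aff_outdegree_activity": "Affirmation outdegree activity",
    "aff_out_isolation_activity": "Affirmation out-isolation activity",
    "aff_same_peer": "Affirmation same peer concentration",
    "cor_reciprocity": "Correction reciprocity",
    "cor_transitive_closure": "Correction transitive closure",
    "cor_three_cycle": "Correction three cycle",
    "cor_indegree_activity": "Correction indegree activity",
    "cor_indegree_popularity": "Correction indegree popularity",
    "cor_outdegree_activity": "Correction outdegree activity",
    "cor_out_isolation_activity": "Correction out-isolation activity",
    "cor_same_peer": "Correction same peer concentration",
    "young_activity": "<1 month activity",
    "young_popularity": "<1 month popularity",
    "senior_activity": ">4 months activity",
    "senior_popularity": ">4 months popularity",
    "admission_homophily": "Admission time homophily",
    "white_activity": "White activity",
    "white_popularity": "White popularity",
    "race_homophily": "Race homophily",
    "age_activity": "Age activity",
    "age_popularity": "Age popularity",
    "age_homophily": "Age homophily",
    "lsir_activity": "LSI-R activity",
    "lsir_popularity": "LSI-R popularity",
    "lsir_similarity": "LSI-R similarity",
    "staff_aff_indegree_activity": "Staff affirmation indegree activity",
    "staff_aff_indegree_popularity": "Staff affirmation indegree popularity",
    "staff_cor_indegree_activity": "Staff correction indegree activity",
    "staff_cor_indegree_popularity": "Staff correction indegree popularity",
    "unit_ht": "Whole unit effect of HT",
    "unit_staff_ht": "Whole unit effect of staff HT",
    "ht_indegree_activity": "HT indegree activity",
    "staff_ht_indegree_activity": "Staff HT indegree activity",
    "ht_outdegree_popularity": "HT outdegree popularity",
    "ht_reciprocity": "HT reciprocity",
}

VARIANCE_NAMES = ["sender_variance", "receiver_variance", "day_variance"]
VARIANCE_LABELS = {
    "sender_variance": "Sender variance component",
    "receiver_variance": "Receiver variance component",
    "day_variance": "Day variance component",
}


@dataclass
class WindowConfig:
    """Tuning constants of the covariate definitions.

    recent_window
        Length (days) of the sliding recency window behind every windowed
        history term.  The default of 1 day means history terms respond to
        the immediately preceding day, the finest memory the one-day log
        resolution supports; at realistic tie densities longer binary
        windows drive the degree indicators toward a constant 1.
    tenure_young_days / tenure_senior_days
        Tenure cut-points: below the first is "new" (<1 month), at or above
        the second is "senior" (>4 months); in between is the reference.
    admission_sim_scale
        Days over which admission-time homophily decays linearly to zero.
    use_counts
        Report windowed counts instead of binary indicators for history
        terms.
    """

    recent_window: int = 1
    tenure_young_days: int = 30
    tenure_senior_days: int = 120
    admission_sim_scale: float = 60.0
    use_counts: bool = False

    def __post_init__(self):
        if self.recent_window < 1:
            raise ValidationError("recent_window must be >= 1")
        if self.tenure_young_days >= self.tenure_senior_days:
            raise ValidationError("tenure_young_days must be < tenure_senior_days")


class HistoryIndex:
    """Incremental windowed aggregates of the two event networks.

    All queries at day ``t`` use only events with day < t (no leakage):
    events are recorded into a per-day buffer and only folded into the
    aggregates when the index is advanced past their day.
    """

    def __init__(self, n_residents: int, window: int):
        self.n = int(n_residents)
        self.window = int(window)
        n = self.n
        self.dyad = np.zeros((2, n, n), dtype=np.int64)  # windowed i->j counts
        self.recv = np.zeros((2, n), dtype=np.int64)  # windowed receipts, staff included
        self.recv_staff = np.zeros((2, n), dtype=np.int64)
        self.sent = np.zeros((2, n), dtype=np.int64)  # windowed resident-sent
        self.ht_dyad = np.zeros((n, n), dtype=np.int64)  # windowed resident HT corrections
        self.ht_recv = np.zeros(n, dtype=np.int64)  # windowed HT receipts, staff included
        self.ht_recv_staff = np.zeros(n, dtype=np.int64)
        self.ht_sent = np.zeros(n, dtype=np.int64)  # windowed resident-sent HT corrections
        self.ht_total = 0
        self.ht_staff_total = 0
        self.ever_sent = np.zeros((2, n), dtype=bool)  # cumulative, never expires
        self._by_day: dict[int, list[tuple[int, int, int, bool]]] = {}
        self._t = 0  # queries are valid at this day
        self._added = 0  # days < _added are folded in
        self._expired = 0  # days < _expired are expired from the window

    def record(self, day: int, sender: int, receiver: int, network: int, headturn: bool) -> None:
        """Queue one event (sender = -1 for staff) for day ``day``."""
        if day < self._added:
            raise ValidationError(f"cannot record into already-consumed day {day}")
        self._by_day.setdefault(day, []).append((sender, receiver, network, bool(headturn)))

    def record_events(self, events: Sequence[EventRecord], index: dict[str, int]) -> None:
        for e in events:
            s = _STAFF if e.staff_sender else index[e.sender_id]
            self.record(e.day, s, index[e.receiver_id], NETWORKS.index(e.network), e.headturn)

    def _apply(self, ev: tuple[int, int, int, bool], sign: int) -> None:
        s, r, k, ht = ev
        if s != _STAFF:
            self.dyad[k, s, r] += sign
            self.sent[k, s] += sign
        self.recv[k, r] += sign
        if s == _STAFF:
            self.recv_staff[k, r] += sign
        if ht:
            self.ht_recv[r] += sign
            self.ht_total += sign
            if s == _STAFF:
                self.ht_recv_staff[r] += sign
                self.ht_staff_total += sign
            else:
                self.ht_sent[s] += sign
                self.ht_dyad[s, r] += sign

    def advance_to(self, t: int) -> None:
        """Make queries valid at day ``t``: window covers [t-window, t-1]."""
        if t < self._t:
            raise ValidationError("HistoryIndex cannot move backwards in time")
        while self._added < t:
            for ev in self._by_day.get(self._added, ()):
                self._apply(ev, +1)
                if ev[0] != _STAFF:
                    self.ever_sent[ev[2], ev[0]] = True
            self._added += 1
        while self._expired < t - self.window:
            for ev in self._by_day.pop(self._expired, ()):
                self._apply(ev, -1)
            self._expired += 1
        self._t = t


class AttributeTables:
    """Roster-derived covariate tables (events never enter these).

    Centring and ranges use the full roster; zero attribute range makes the
    corresponding similarity identically 1 (all actors identical).
    """

    def __init__(self, roster: Sequence[ResidentRecord], w: WindowConfig):
        self.entry = np.array([r.entry_day for r in roster], dtype=float)
        age = np.array([r.age for r in roster], dtype=float)
        lsir = np.array([r.lsir for r in roster], dtype=float)
        self.white = np.array([r.race_white for r in roster], dtype=float)
        self.age_c = age - age.mean()
        self.lsir_c = lsir - lsir.mean()
        self.race_hom = (self.white[:, None] == self.white[None, :]).astype(float)
        self.age_hom = _range_similarity(age)
        self.lsir_sim = _range_similarity(lsir)
        self.adm_hom = np.maximum(
            0.0, 1.0 - np.abs(self.entry[:, None] - self.entry[None, :]) / w.admission_sim_scale
        )


def _range_similarity(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min() if len(x) else 0.0
    if rng == 0:
        return np.ones((len(x), len(x)))
    return 1.0 - np.abs(x[:, None] - x[None, :]) / rng


def _bz(x, use_counts: bool):
    return np.asarray(x, dtype=float) if use_counts else (np.asarray(x) > 0).astype(float)


def day_design_matrix(
    h: HistoryIndex,
    present: np.ndarray,
    t: int,
    attrs: AttributeTables,
    w: WindowConfig,
    columns: Sequence[str],
):
    """Vectorised covariate matrix for all ordered dyads present on day ``t``.

    The index must already be advanced to ``t``.  Returns (senders,
    receivers, X) where senders/receivers are global resident indices of the
    n(n-1) ordered dyads and X has one column per requested covariate.
    """
    p = np.asarray(present, dtype=int)
    n = len(p)
    ixg = np.ix_(p, p)
    mask = ~np.eye(n, dtype=bool)
    Si, Rj = np.meshgrid(p, p, indexing="ij")
    uc = w.use_counts

    def col(v):  # activity: depends on sender i only
        return np.broadcast_to(np.asarray(v, dtype=float)[:, None], (n, n))

    def row(v):  # popularity: depends on receiver j only
        return np.broadcast_to(np.asarray(v, dtype=float)[None, :], (n, n))

    cache: dict[str, np.ndarray] = {}

    def triad(k):  # distinct-intermediary counts, full roster then sliced
        key = f"triad{k}"
        if key not in cache:
            Wb = (h.dyad[k] > 0).astype(np.int64)
            cache[key] = Wb @ Wb
        return cache[key]

    def build(name: str) -> np.ndarray:
        if name == "intercept":
            return np.ones((n, n))
        for k, pre in enumerate(("aff", "cor")):
            if name == f"{pre}_reciprocity":
                return _bz(h.dyad[k].T[ixg], uc)
            if name == f"{pre}_same_peer":
                return _bz(h.dyad[k][ixg], uc)
            if name == f"{pre}_transitive_closure":
                return _bz(triad(k)[ixg], uc)
            if name == f"{pre}_three_cycle":
                return _bz(triad(k).T[ixg], uc)
            if name == f"{pre}_indegree_activity":
                return _bz(h.recv[k][p][:, None] - h.dyad[k].T[ixg], uc)
            if name == f"{pre}_indegree_popularity":
                return _bz(h.recv[k][p][None, :] - h.dyad[k][ixg], uc)
            if name == f"{pre}_outdegree_activity":
                return _bz(h.sent[k][p][:, None] - h.dyad[k][ixg], uc)
            if name == f"{pre}_out_isolation_activity":
                return col(~h.ever_sent[k][p])
            if name == f"staff_{pre}_indegree_activity":
                return col(_bz(h.recv_staff[k][p], uc))
            if name == f"staff_{pre}_indegree_popularity":
                return row(_bz(h.recv_staff[k][p], uc))
        if name == "unit_ht":
            return col(_bz(h.ht_total - h.ht_recv[p], uc))
        if name == "unit_staff_ht":
            return col(_bz(h.ht_staff_total - h.ht_recv_staff[p], uc))
        if name == "ht_indegree_activity":
            return col(_bz(h.ht_recv[p], uc))
        if name == "staff_ht_indegree_activity":
            return col(_bz(h.ht_recv_staff[p], uc))
        if name == "ht_outdegree_popularity":
            return row(_bz(h.ht_sent[p], uc))
        if name == "ht_reciprocity":
            return _bz(h.ht_dyad.T[ixg], uc)
        tenure = t - attrs.entry[p]
        if name == "young_activity":
            return col(tenure < w.tenure_young_days)
        if name == "young_popularity":
            return row(tenure < w.tenure_young_days)
        if name == "senior_activity":
            return col(tenure >= w.tenure_senior_days)
        if name == "senior_popularity":
            return row(tenure >= w.tenure_senior_days)
        if name == "admission_homophily":
            return attrs.adm_hom[ixg]
        if name == "white_activity":
            return col(attrs.white[p])
        if name == "white_popularity":
            return row(attrs.white[p])
        if name == "race_homophily":
            return attrs.race_hom[ixg]
        if name == "age_activity":
            return col(attrs.age_c[p])
        if name == "age_popularity":
            return row(attrs.age_c[p])
        if name == "age_homophily":
            return attrs.age_hom[ixg]
        if name == "lsir_activity":
            return col(attrs.lsir_c[p])
        if name == "lsir_popularity":
            return row(attrs.lsir_c[p])
        if name == "lsir_similarity":
            return attrs.lsir_sim[ixg]
        raise ValidationError(f"unknown covariate {name!r}")

    X = np.empty((n * (n - 1), len(columns)))
    for ci, name in enumerate(columns):
        X[:, ci] = np.asarray(build(name), dtype=float)[mask]
    return Si[mask], Rj[mask], X


# ---------------------------------------------------------------------------
# Scalar per-dyad accessors (one observation at a time; same definitions).
# ---------------------------------------------------------------------------


def dyadic_stats(h: HistoryIndex, i: int, j: int, t: int, w: WindowConfig) -> dict:
    """Reciprocity, same-peer concentration, and HT reciprocity for (i, j, t)."""
    if i == j:
        raise ValidationError("dyadic statistics need two distinct residents")
    h.advance_to(t)
    uc = w.use_counts
    out = {}
    for k, pre in enumerate(("aff", "cor")):
        out[f"{pre}_reciprocity"] = float(_bz(h.dyad[k, j, i], uc))
        out[f"{pre}_same_peer"] = float(_bz(h.dyad[k, i, j], uc))
    out["ht_reciprocity"] = float(_bz(h.ht_dyad[j, i], uc))
    return out


def triadic_stats(h: HistoryIndex, i: int, j: int, t: int, w: WindowConfig) -> dict:
    """Transitive closure (i->k, k->j) and three-cycle (j->k, k->i) terms."""
    h.advance_to(t)
    out = {}
    for k, pre in enumerate(("aff", "cor")):
        Wb = h.dyad[k] > 0
        trans = int(np.sum(Wb[i] & Wb[:, j]))
        cyc = int(np.sum(Wb[j] & Wb[:, i]))
        out[f"{pre}_transitive_closure"] = float(_bz(trans, w.use_counts))
        out[f"{pre}_three_cycle"] = float(_bz(cyc, w.use_counts))
    return out


def degree_stats(h: HistoryIndex, i: int, j: int, t: int, w: WindowConfig) -> dict:
    """Degree, out-isolation, staff-differential, and head-turn terms."""
    h.advance_to(t)
    uc = w.use_counts
    out = {}
    for k, pre in enumerate(("aff", "cor")):
        out[f"{pre}_indegree_activity"] = float(_bz(h.recv[k, i] - h.dyad[k, j, i], uc))
        out[f"{pre}_indegree_popularity"] = float(_bz(h.recv[k, j] - h.dyad[k, i, j], uc))
        out[f"{pre}_outdegree_activity"] = float(_bz(h.sent[k, i] - h.dyad[k, i, j], uc))
        out[f"{pre}_out_isolation_activity"] = float(not h.ever_sent[k, i])
        out[f"staff_{pre}_indegree_activity"] = float(_bz(h.recv_staff[k, i], uc))
        out[f"staff_{pre}_indegree_popularity"] = float(_bz(h.recv_staff[k, j], uc))
    out["unit_ht"] = float(_bz(h.ht_total - h.ht_recv[i], uc))
    out["unit_staff_ht"] = float(_bz(h.ht_staff_total - h.ht_recv_staff[i], uc))
    out["ht_indegree_activity"] = float(_bz(h.ht_recv[i], uc))
    out["staff_ht_indegree_activity"] = float(_bz(h.ht_recv_staff[i], uc))
    out["ht_outdegree_popularity"] = float(_bz(h.ht_sent[j], uc))
    return out


def tenure_stats(
    grid: PresenceGrid, roster: Sequence[ResidentRecord], i: int, j: int, t: int, w: WindowConfig
) -> dict:
    """Tenure-category indicators; mid-tenure is the (all-zero) reference."""
    ti = t - roster[i].entry_day
    tj = t - roster[j].entry_day
    return {
        "young_activity": float(ti < w.tenure_young_days),
        "young_popularity": float(tj < w.tenure_young_days),
        "senior_activity": float(ti >= w.tenure_senior_days),
        "senior_popularity": float(tj >= w.tenure_senior_days),
    }


def attribute_stats(
    roster: Sequence[ResidentRecord], i: int, j: int, w: WindowConfig, attrs: AttributeTables | None = None
) -> dict:
    if attrs is None:
        attrs = AttributeTables(roster, w)
    return {
        "admission_homophily": float(attrs.adm_hom[i, j]),
        "white_activity": float(attrs.white[i]),
        "white_popularity": float(attrs.white[j]),
        "race_homophily": float(attrs.race_hom[i, j]),
        "age_activity": float(attrs.age_c[i]),
        "age_popularity": float(attrs.age_c[j]),
        "age_homophily": float(attrs.age_hom[i, j]),
        "lsir_activity": float(attrs.lsir_c[i]),
        "lsir_popularity": float(attrs.lsir_c[j]),
        "lsir_similarity": float(attrs.lsir_sim[i, j]),
    }


def covariate_vector(
    h: HistoryIndex,
    grid: PresenceGrid,
    roster: Sequence[ResidentRecord],
    i: int,
    j: int,
    t: int,
    w: WindowConfig,
    attrs: AttributeTables | None = None,
) -> dict:
    """The full named predictor vector for one dyad-day (scalar route)."""
    out = {"intercept": 1.0}
    out.update(dyadic_stats(h, i, j, t, w))
    out.update(triadic_stats(h, i, j, t, w))
    out.update(degree_stats(h, i, j, t, w))
    out.update(tenure_stats(grid, roster, i, j, t, w))
    out.update(attribute_stats(roster, i, j, w, attrs))
    return {k: out[k] for k in COVARIATE_NAMES}


def assemble_design(
    events: Sequence[EventRecord],
    grid: PresenceGrid,
    roster: Sequence[ResidentRecord],
    w: WindowConfig | None = None,
    columns: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Design tables for the two tie models (identical covariate columns).

    One row per ordered co-present resident dyad per day per network, with
    the binary tie outcome and every requested covariate computed from
    history strictly before that day.
    """
    w = w or WindowConfig()
    columns = list(columns) if columns is not None else list(COVARIATE_NAMES)
    attrs = AttributeTables(roster, w)
    h = HistoryIndex(grid.n_residents, w.recent_window)
    h.record_events(events, grid.index)
    tied: dict[int, set] = {}
    for e in events:
        if not e.staff_sender:
            tied.setdefault(e.day, set()).add(
                (grid.index[e.sender_id], grid.index[e.receiver_id], NETWORKS.index(e.network))
            )
    parts = {net: {"S": [], "R": [], "day": [], "X": [], "y": []} for net in NETWORKS}
    for t in range(grid.horizon):
        present = grid.present_idx(t)
        if len(present) < 2:
            continue
        h.advance_to(t)
        S, R, X = day_design_matrix(h, present, t, attrs, w, columns)
        day_ties = tied.get(t, set())
        for k, net in enumerate(NETWORKS):
            y = np.fromiter(
                ((s, r, k) in day_ties for s, r in zip(S, R)), dtype=bool, count=len(S)
            )
            part = parts[net]
            part["S"].append(S)
            part["R"].append(R)
            part["day"].append(np.full(len(S), t))
            part["X"].append(X)
            part["y"].append(y)
    if not parts[AFFIRMATION]["S"]:
        raise ValidationError("risk set is empty on every day; nothing to model")
    ids = np.asarray(grid.ids, dtype=object)
    out = {}
    for net in NETWORKS:
        part = parts[net]
        S = np.concatenate(part["S"])
        R = np.concatenate(part["R"])
        df = pd.DataFrame(
            {
                "sender": ids[S],
                "receiver": ids[R],
                "day": np.concatenate(part["day"]),
                "network": net,
                "tie": np.concatenate(part["y"]),
            }
        )
        X = np.vstack(part["X"])
        for ci, name in enumerate(columns):
            df[name] = X[:, ci]
        out[net] = df
    return out
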