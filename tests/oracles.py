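"""Independent brute-force oracles used to check the covariate engine.

Everything here recomputes statistics by scanning the raw event list per
query, straight from the definitions, with no shared code or state with
the incremental ``HistoryIndex`` implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

STAFF = -1
AFF, COR = 0, 1


@dataclass(frozen=True)
class Ev:
    day: int
    s: int  # sender index, STAFF for staff
    r: int
    net: int
    ht: bool = False


def _code(x, use_counts):
    return float(x) if use_counts else float(x > 0)


def naive_covariates(events, roster, i, j, t, w) -> dict:
    """All history/tenure/attribute covariates for dyad (i, j) at day t.

    ``events`` is a list of Ev; ``roster`` a list of ResidentRecord.
    """
    win = [e for e in events if t - w.recent_window <= e.day <= t - 1]
    prior = [e for e in events if e.day < t]
    uc = w.use_counts
    out = {"intercept": 1.0}
    for net, pre in ((AFF, "aff"), (COR, "cor")):
        wn = [e for e in win if e.net == net]
        out[f"{pre}_reciprocity"] = _code(sum(e.s == j and e.r == i for e in wn), uc)
        out[f"{pre}_same_peer"] = _code(sum(e.s == i and e.r == j for e in wn), uc)
        heads = {e.r for e in wn if e.s == i}
        tails = {e.s for e in wn if e.r == j and e.s != STAFF}
        out[f"{pre}_transitive_closure"] = _code(len((heads & tails) - {i, j}), uc)
        heads2 = {e.r for e in wn if e.s == j}
        tails2 = {e.s for e in wn if e.r == i and e.s != STAFF}
        out[f"{pre}_three_cycle"] = _code(len((heads2 & tails2) - {i, j}), uc)
        out[f"{pre}_indegree_activity"] = _code(sum(e.r == i and e.s != j for e in wn), uc)
        out[f"{pre}_indegree_popularity"] = _code(sum(e.r == j and e.s != i for e in wn), uc)
        out[f"{pre}_outdegree_activity"] = _code(sum(e.s == i and e.r != j for e in wn), uc)
        out[f"{pre}_out_isolation_activity"] = float(
            not any(e.s == i and e.net == net for e in prior)
        )
        out[f"staff_{pre}_indegree_activity"] = _code(
            sum(e.r == i and e.s == STAFF for e in wn), uc
        )
        out[f"staff_{pre}_indegree_popularity"] = _code(
            sum(e.r == j and e.s == STAFF for e in wn), uc
        )
    hts = [e for e in win if e.ht]
    out["unit_ht"] = _code(sum(e.r != i for e in hts), uc)
    out["unit_staff_ht"] = _code(sum(e.r != i and e.s == STAFF for e in hts), uc)
    out["ht_indegree_activity"] = _code(sum(e.r == i for e in hts), uc)
    out["staff_ht_indegree_activity"] = _code(sum(e.r == i and e.s == STAFF for e in hts), uc)
    out["ht_outdegree_popularity"] = _code(sum(e.s == j for e in hts), uc)
    out["ht_reciprocity"] = _code(sum(e.s == j and e.r == i for e in hts), uc)

    ti, tj = t - roster[i].entry_day, t - roster[j].entry_day
    out["young_activity"] = float(ti < w.tenure_young_days)
    out["young_popularity"] = float(tj < w.tenure_young_days)
    out["senior_activity"] = float(ti >= w.tenure_senior_days)
    out["senior_popularity"] = float(tj >= w.tenure_senior_days)

    ages = [r.age for r in roster]
    lsirs = [r.lsir for r in roster]
    entries = [r.entry_day for r in roster]
    age_rng = max(ages) - min(ages)
    lsir_rng = max(lsirs) - min(lsirs)
    out["admission_homophily"] = max(0.0, 1.0 - abs(entries[i] - entries[j]) / w.admission_sim_scale)
    out["white_activity"] = float(roster[i].race_white)
    out["white_popularity"] = float(roster[j].race_white)
    out["race_homophily"] = float(roster[i].race_white == roster[j].race_white)
    mean_age = sum(ages) / len(ages)
    mean_lsir = sum(lsirs) / len(lsirs)
    out["age_activity"] = roster[i].age - mean_age
    out["age_popularity"] = roster[j].age - mean_age
    out["age_homophily"] = 1.0 if age_rng == 0 else 1.0 - abs(roster[i].age - roster[j].age) / age_rng
    out["lsir_activity"] = roster[i].lsir - mean_lsir
    out["lsir_popularity"] = roster[j].lsir - mean_lsir
    out["lsir_similarity"] = (
        1.0 if lsir_rng == 0 else 1.0 - abs(roster[i].lsir - roster[j].lsir) / lsir_rng
    )
    return out


def random_history(rng, n_residents, horizon, rate=0.04, staff_rate=0.5, p_ht=0.2):
    """A random event history: resident dyad events plus staff events."""
    events = []
    for t in range(horizon):
        for i in range(n_residents):
            for j in range(n_residents):
                if i == j:
                    continue
                for net in (AFF, COR):
                    if rng.random() < rate:
                        ht = bool(net == COR and rng.random() < p_ht)
                        events.append(Ev(t, i, j, net, ht))
        for net in (AFF, COR):
            if rng.random() < staff_rate:
                tgt = int(rng.integers(n_residents))
                ht = bool(net == COR and rng.random() < p_ht)
                events.append(Ev(t, STAFF, tgt, net, ht))
    return events
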