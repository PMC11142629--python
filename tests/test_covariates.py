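"""Covariate definitions against brute-force oracles and invariants."""

import numpy as np
import pytest

from tcnet.covariates import (
    COVARIATE_NAMES,
    AttributeTables,
    HistoryIndex,
    WindowConfig,
    assemble_design,
    attribute_stats,
    covariate_vector,
    day_design_matrix,
    dyadic_stats,
    degree_stats,
    tenure_stats,
    triadic_stats,
)
from tcnet.event_data import (
    AFFIRMATION,
    CORRECTION,
    EventRecord,
    ResidentRecord,
    ValidationError,
    build_presence_grid,
)

from conftest import index_from_events, make_roster
from oracles import AFF, COR, STAFF, Ev, naive_covariates, random_history


class TestScalarDefinitions:
    """Hand-checkable cases straight from the definitions."""

    def test_empty_history_gives_all_zero_dyadic_terms(self, default_window):
        h = HistoryIndex(4, default_window.recent_window)
        out = dyadic_stats(h, 0, 1, 10, default_window)
        assert all(v == 0.0 for v in out.values())

    def test_reciprocity_window_boundaries(self):
        w = WindowConfig(recent_window=14)
        h = index_from_events([Ev(9, 1, 0, AFF)], 4, 14)
        assert dyadic_stats(h, 0, 1, 10, w)["aff_reciprocity"] == 1.0
        assert dyadic_stats(h, 0, 1, 10, w)["cor_reciprocity"] == 0.0
        h = index_from_events([Ev(9, 1, 0, AFF)], 4, 14)
        # 20 days later the event has slid out of the window
        assert dyadic_stats(h, 0, 1, 29, w)["aff_reciprocity"] == 0.0

    def test_transitive_and_cycle_orientations(self, default_window):
        w = default_window
        h = index_from_events([Ev(9, 0, 2, AFF), Ev(9, 2, 1, AFF)], 4, w.recent_window)
        out = triadic_stats(h, 0, 1, 10, w)
        assert out["aff_transitive_closure"] == 1.0
        assert out["aff_three_cycle"] == 0.0
        h = index_from_events([Ev(9, 1, 2, AFF), Ev(9, 2, 0, AFF)], 4, w.recent_window)
        out = triadic_stats(h, 0, 1, 10, w)
        assert out["aff_three_cycle"] == 1.0
        assert out["aff_transitive_closure"] == 0.0

    def test_virgin_resident_is_out_isolated_with_zero_degrees(self, default_window):
        h = HistoryIndex(4, default_window.recent_window)
        out = degree_stats(h, 0, 1, 5, default_window)
        assert out["aff_out_isolation_activity"] == 1.0
        assert out["cor_out_isolation_activity"] == 1.0
        assert out["aff_indegree_activity"] == 0.0

    def test_staff_receipt_counts_in_base_and_staff_terms(self, default_window):
        # differential coding: a staff correction raises both indicators
        h = index_from_events([Ev(4, STAFF, 0, COR)], 4, default_window.recent_window)
        out = degree_stats(h, 0, 1, 5, default_window)
        assert out["cor_indegree_activity"] == 1.0
        assert out["staff_cor_indegree_activity"] == 1.0
        assert out["aff_indegree_activity"] == 0.0

    def test_out_isolation_is_cumulative_not_windowed(self):
        w = WindowConfig(recent_window=1)
        h = index_from_events([Ev(0, 0, 2, AFF)], 4, 1)
        out = degree_stats(h, 0, 1, 50, w)
        assert out["aff_out_isolation_activity"] == 0.0  # sent once, long ago
        assert out["aff_outdegree_activity"] == 0.0  # but nothing recent

    def test_tenure_categories(self, small_roster, small_grid, default_window):
        w = default_window
        for t, young, senior in [(10, 1.0, 0.0), (60, 0.0, 0.0), (130, 0.0, 1.0)]:
            out = tenure_stats(small_grid, small_roster, 0, 1, t, w)
            assert out["young_activity"] == young
            assert out["senior_activity"] == senior

    def test_twins_have_unit_similarity(self, default_window):
        twins = [
            ResidentRecord("a", 0, 100, 30.0, True, 25),
            ResidentRecord("b", 0, 100, 30.0, True, 25),
            ResidentRecord("c", 0, 100, 40.0, False, 35),
        ]
        out = attribute_stats(twins, 0, 1, default_window)
        for key in ("race_homophily", "age_homophily", "lsir_similarity", "admission_homophily"):
            assert out[key] == 1.0

    def test_age_homophily_boundary_and_admission_scale(self, default_window):
        roster = [
            ResidentRecord("a", 0, 100, 20.0, True, 20),
            ResidentRecord("b", 30, 100, 45.0, True, 30),
        ]
        out = attribute_stats(roster, 0, 1, default_window)
        assert out["age_homophily"] == 0.0  # extremes of the roster range
        assert out["admission_homophily"] == pytest.approx(0.5)  # 30 d apart, 60 d scale

    def test_zero_attribute_range_defines_similarity_one(self, default_window):
        roster = [ResidentRecord(c, 0, 100, 30.0, True, 25) for c in "ab"]
        out = attribute_stats(roster, 0, 1, default_window)
        assert out["lsir_similarity"] == 1.0 and out["age_homophily"] == 1.0

    def test_same_resident_dyad_rejected(self, default_window):
        h = HistoryIndex(4, 1)
        with pytest.raises(ValidationError):
            dyadic_stats(h, 2, 2, 5, default_window)


@pytest.mark.parametrize("use_counts", [False, True])
@pytest.mark.parametrize("window", [1, 3, 14])
def test_incremental_index_matches_naive_scan(use_counts, window):
    """Every covariate from the incremental index equals a per-query scan."""
    rng = np.random.default_rng(42 + window)
    for rep in range(30):
        n = int(rng.integers(3, 9))
        horizon = int(rng.integers(5, 40))
        roster = make_roster(n, horizon, rng, staggered=False)
        w = WindowConfig(recent_window=window, use_counts=use_counts)
        events = random_history(rng, n, horizon, rate=0.08)
        h = index_from_events(events, n, window)
        grid = build_presence_grid(roster, horizon)
        attrs = AttributeTables(roster, w)
        for t in sorted(rng.integers(1, horizon, size=4)):
            i, j = rng.choice(n, 2, replace=False)
            got = covariate_vector(h, grid, roster, int(i), int(j), int(t), w, attrs)
            want = naive_covariates(events, roster, int(i), int(j), int(t), w)
            for name in COVARIATE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-12), (name, i, j, t)


def test_vectorised_day_matrix_matches_scalar_route(default_window):
    rng = np.random.default_rng(7)
    n, horizon = 8, 30
    roster = make_roster(n, horizon, rng, staggered=False)
    w = WindowConfig(recent_window=3)
    events = random_history(rng, n, horizon, rate=0.1)
    grid = build_presence_grid(roster, horizon)
    attrs = AttributeTables(roster, w)
    h = index_from_events(events, n, 3)
    for t in (5, 17, 29):
        h2 = index_from_events(events, n, 3)
        h2.advance_to(t)
        S, R, X = day_design_matrix(h2, np.arange(n), t, attrs, w, COVARIATE_NAMES)
        for k in range(len(S)):
            want = covariate_vector(h, grid, roster, int(S[k]), int(R[k]), t, w, attrs)
            np.testing.assert_allclose(X[k], [want[c] for c in COVARIATE_NAMES], atol=1e-12)


class TestInvariants:
    def test_no_leakage_from_future_events(self, default_window):
        rng = np.random.default_rng(3)
        n, horizon, t = 6, 30, 15
        roster = make_roster(n, horizon, rng, staggered=False)
        events = random_history(rng, n, horizon, rate=0.1)
        past_only = [e for e in events if e.day < t]
        w = WindowConfig(recent_window=5)
        grid = build_presence_grid(roster, horizon)
        attrs = AttributeTables(roster, w)
        full = index_from_events(events, n, 5)
        trunc = index_from_events(past_only, n, 5)
        for i, j in [(0, 1), (2, 5), (4, 3)]:
            assert covariate_vector(full, grid, roster, i, j, t, w, attrs) == covariate_vector(
                trunc, grid, roster, i, j, t, w, attrs
            )

    def test_homophily_symmetric_activity_sender_only_popularity_receiver_only(
        self, default_window
    ):
        rng = np.random.default_rng(9)
        roster = make_roster(6, 50, rng)
        a_ij = attribute_stats(roster, 1, 4, default_window)
        a_ji = attribute_stats(roster, 4, 1, default_window)
        a_ik = attribute_stats(roster, 1, 2, default_window)
        for key in ("race_homophily", "age_homophily", "lsir_similarity", "admission_homophily"):
            assert a_ij[key] == a_ji[key]
        for key in ("white_activity", "age_activity", "lsir_activity"):
            assert a_ij[key] == a_ik[key]  # depends only on the sender
        for key in ("white_popularity", "age_popularity", "lsir_popularity"):
            assert a_ij[key] == a_ji[key.replace("popularity", "activity")]

    def test_reciprocity_monotone_in_added_reverse_event(self, default_window):
        w = WindowConfig(recent_window=7)
        base = [Ev(2, 0, 2, AFF)]
        h0 = index_from_events(base, 4, 7)
        h1 = index_from_events(base + [Ev(5, 1, 0, AFF)], 4, 7)
        r0 = dyadic_stats(h0, 0, 1, 8, w)["aff_reciprocity"]
        r1 = dyadic_stats(h1, 0, 1, 8, w)["aff_reciprocity"]
        assert (r0, r1) == (0.0, 1.0)

    def test_index_refuses_to_rewind(self):
        h = HistoryIndex(3, 2)
        h.advance_to(10)
        with pytest.raises(ValidationError):
            h.advance_to(5)
        with pytest.raises(ValidationError):
            h.record(3, 0, 1, AFF, False)


class TestAssembleDesign:
    def test_row_counts_and_all_zero_history_without_events(self):
        roster = make_roster(2, 3, staggered=False)
        grid = build_presence_grid(roster, 3)
        designs = assemble_design([], grid, roster)
        windowed = [
            c
            for c in COVARIATE_NAMES
            if c.startswith(("aff_", "cor_", "ht_", "staff_", "unit_"))
            and "out_isolation" not in c
        ]
        for net, df in designs.items():
            assert len(df) == 3 * 2  # 2 ordered dyads x 3 days
            assert not df[windowed].to_numpy().any()
            assert df["aff_out_isolation_activity"].eq(1).all()
            assert df["cor_out_isolation_activity"].eq(1).all()

    def test_row_count_matches_presence_combinatorics(self):
        rng = np.random.default_rng(11)
        horizon = 20
        roster = make_roster(7, horizon, rng, staggered=True)
        grid = build_presence_grid(roster, horizon)
        designs = assemble_design([], grid, roster, columns=["intercept"])
        expected = sum(
            len(grid.present_idx(t)) * (len(grid.present_idx(t)) - 1)
            for t in range(horizon)
            if len(grid.present_idx(t)) >= 2
        )
        assert len(designs[AFFIRMATION]) == expected == len(designs[CORRECTION])

    def test_shifting_events_later_preserves_earlier_rows(self):
        roster = make_roster(4, 20, staggered=False)
        grid = build_presence_grid(roster, 20)
        events = [
            EventRecord("r00", "r01", 5, AFFIRMATION),
            EventRecord("r01", "r02", 9, CORRECTION),
        ]
        shifted = [
            EventRecord(e.sender_id, e.receiver_id, e.day + 1, e.network) for e in events
        ]
        d0 = assemble_design(events, grid, roster)[AFFIRMATION]
        d1 = assemble_design(shifted, grid, roster)[AFFIRMATION]
        cols = [c for c in COVARIATE_NAMES]
        before = d0.day < 5
        np.testing.assert_array_equal(d0.loc[before, cols].values, d1.loc[before, cols].values)

    def test_empty_risk_set_everywhere_is_fatal(self):
        roster = [
            ResidentRecord("a", 0, 5, 30.0, True, 20),
            ResidentRecord("b", 5, 10, 25.0, True, 22),
        ]
        grid = build_presence_grid(roster, 10)
        with pytest.raises(ValidationError, match="risk set"):
            assemble_design([], grid, roster)
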