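"""Scripted refinement sessions: selections, edits, audit log, replay."""

import pandas as pd
import pytest

from binref import BinAssignmentTable, BinrefError, escg_stats
from binref.io import UNBINNED
from binref.refinement import REFINED, RefinementSession, replay


@pytest.fixture
def session(small_community, small_features):
    table = BinAssignmentTable(data=small_community.truth.data.copy())
    return RefinementSession(
        table, features=small_features, escg=small_community.escg
    )


class TestSelect:
    def test_interval_predicate_matches_brute_force_filter(self, session):
        gc = session.features.data["gc"]
        lo, hi = gc.quantile(0.25), gc.quantile(0.75)
        sel = session.select([("gc", lo, hi)])
        oracle = {cid for cid, v in gc.items() if lo <= v <= hi}
        assert sel.ids == frozenset(oracle)
        assert sel.count == len(oracle)

    def test_empty_predicate_list_selects_working_set(self, session):
        assert session.select([]).ids == frozenset(session.working_set)

    def test_disjoint_intervals_conjunction_is_empty(self, session):
        sel = session.select([("gc", 0.0, 0.3), ("gc", 0.6, 1.0)])
        assert sel.count == 0

    def test_bin_predicate(self, session):
        sel = session.select([("truth", {"genome1"})])
        truth = session.assignments.column("truth")
        assert sel.ids == frozenset(truth.index[truth == "genome1"])

    def test_predicate_order_does_not_matter(self, session):
        p1, p2 = ("gc", 0.3, 0.6), ("truth", {"genome1", "genome2"})
        assert session.select([p1, p2]).ids == session.select([p2, p1]).ids

    def test_unknown_variable_is_error(self, session):
        with pytest.raises(BinrefError, match="nope"):
            session.select([("nope", 0, 1)])


class TestKeepRemove:
    def test_keep_all_is_identity(self, session):
        before = set(session.working_set)
        session.keep(session.select([]))
        assert session.working_set == before

    def test_remove_all_empties_working_set(self, session):
        session.remove(session.select([]))
        assert session.working_set == set()

    def test_keep_then_remove_same_selection_is_empty(self, session):
        sel = session.select([("truth", {"genome1"})])
        session.keep(sel)
        session.remove(session.select([]))
        assert session.working_set == set()

    def test_keep_scopes_subsequent_selections(self, session):
        sel = session.select([("truth", {"genome1"})])
        session.keep(sel)
        assert session.select([]).ids == sel.ids
        # underlying tables untouched
        assert len(session.assignments.data) > len(sel.ids)


class TestAssign:
    def test_assign_then_unassign_restores_column(self, session):
        before = session.refined_column()
        sel = session.select([("truth", {"genome2"})])
        session.assign(sel, "bin_x")
        session.unassign(session.select([("refined", {"bin_x"})]))
        pd.testing.assert_series_equal(session.refined_column(), before)

    def test_live_feedback_equals_direct_escg_stats(self, session, small_community):
        members = small_community.truth.bins("truth")["genome1"]
        sel = session.select([("truth", {"genome1"})])
        quality = session.assign(sel, "refined_1")
        direct = escg_stats(members, small_community.escg)
        assert quality.completeness == direct.completeness
        assert quality.contamination == direct.contamination

    def test_overlapping_assign_moves_contigs(self, session):
        all_sel = session.select([])
        session.assign(all_sel, "first")
        sub = session.select([("truth", {"genome3"})])
        session.assign(sub, "second")
        col = session.refined_column()
        assert set(col.unique()) == {"first", "second"}
        assert (col.loc[list(sub.ids)] == "second").all()

    def test_refined_column_always_partitions_contigs(self, session):
        session.assign(session.select([("truth", {"genome1"})]), "a")
        session.assign(session.select([("gc", 0.0, 0.5)]), "b")
        session.remove(session.select([("truth", {"genome2"})]))
        col = session.refined_column()
        assert set(col.index) == set(session.assignments.data.index)
        assert col.notna().all()

    def test_empty_selection_assignment_is_error(self, session):
        empty = session.select([("gc", 2.0, 3.0)])
        with pytest.raises(BinrefError):
            session.assign(empty, "x")

    def test_source_method_seeds_refined_column(self, small_community):
        table = BinAssignmentTable(data=small_community.truth.data.copy())
        session = RefinementSession(table, source_method="truth")
        pd.testing.assert_series_equal(
            session.refined_column(),
            small_community.truth.data["truth"],
            check_names=False,
        )


class TestReplay:
    def _scripted(self, small_community, small_features):
        table = BinAssignmentTable(data=small_community.truth.data.copy())
        session = RefinementSession(
            table, features=small_features, escg=small_community.escg
        )
        session.assign(session.select([("truth", {"genome1"})]), "r1")
        session.keep(session.select([("gc", 0.0, 0.6)]))
        session.assign(session.select([]), "r2")
        session.remove(session.select([("refined", {"r2"})]))
        session.tag("r1", "looks clean")
        return session

    def test_replay_reproduces_assignments_and_hash(
        self, small_community, small_features
    ):
        original = self._scripted(small_community, small_features)
        fresh = BinAssignmentTable(data=small_community.truth.data.copy())
        replayed = replay(fresh, original.audit_log, features=small_features)
        pd.testing.assert_series_equal(
            replayed.refined_column(), original.refined_column()
        )
        assert replayed.refined_hash() == original.refined_hash()
        assert replayed.tags == original.tags

    def test_empty_log_is_initial_state(self, small_community):
        table = BinAssignmentTable(data=small_community.truth.data.copy())
        session = replay(table, [])
        assert (session.refined_column() == UNBINNED).all()
        assert session.audit_log == []

    def test_truncated_log_yields_intermediate_state(
        self, small_community, small_features
    ):
        original = self._scripted(small_community, small_features)
        fresh = BinAssignmentTable(data=small_community.truth.data.copy())
        partial = replay(fresh, original.audit_log[:1], features=small_features)
        col = partial.refined_column()
        assert set(col.unique()) == {"r1", UNBINNED}

    def test_corrupted_event_names_index(self, small_community):
        table = BinAssignmentTable(data=small_community.truth.data.copy())
        log = [{"op": "assign", "args": {}}]  # missing ids/bin
        with pytest.raises(BinrefError, match="index 0"):
            replay(table, log)

    def test_unknown_op_rejected(self, small_community):
        table = BinAssignmentTable(data=small_community.truth.data.copy())
        with pytest.raises(BinrefError, match="frobnicate"):
            replay(table, [{"op": "frobnicate", "args": {}}])
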