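import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pridenet.matrices import build_interaction_matrix
from pridenet.observations import (
    GroupScan,
    Individual,
    InteractionEvent,
    ObservationError,
    ObservationSet,
    data_point_accounting,
    deduplicate_bouts,
    read_observations,
    subset_observations,
    write_observations,
)

from conftest import make_individual, random_events

T0 = dt.datetime(2012, 1, 6, 7, 0)


def ev(seconds, initiator="A", recipient="B", behavior="play"):
    return InteractionEvent(T0 + dt.timedelta(seconds=seconds), initiator, recipient, behavior)


class TestValidation:
    def test_self_interaction_rejected(self):
        with pytest.raises(ObservationError, match="initiator == recipient"):
            ev(0, "A", "A")

    def test_unknown_behavior_rejected(self):
        with pytest.raises(ObservationError, match="unknown behavior"):
            InteractionEvent(T0, "A", "B", "wrestling_match")

    def test_scan_present_absent_disjoint(self):
        with pytest.raises(ObservationError, match="present and absent"):
            GroupScan("s", T0, frozenset("AB"), frozenset("B"))

    def test_roster_needs_age_information(self):
        with pytest.raises(ObservationError, match="birth_date or age_class"):
            Individual("A", "female")

    def test_unknown_id_in_events_names_id(self, toy_roster):
        with pytest.raises(ObservationError, match="ZZ"):
            ObservationSet(roster=toy_roster, events=(ev(0, "A", "ZZ"),))

    def test_duplicate_roster_ids_rejected(self):
        two = (make_individual("A"), make_individual("A"))
        with pytest.raises(ObservationError, match="duplicate"):
            ObservationSet(roster=two)

    def test_asymmetric_kinship_rejected(self, toy_roster):
        import pandas as pd

        k = pd.DataFrame(
            [[1, 0.5], [0.25, 1]], index=["A", "B"], columns=["A", "B"], dtype=float
        )
        with pytest.raises(ObservationError, match="symmetric"):
            ObservationSet(roster=toy_roster, kinship=k)


class TestFileIO:
    def test_round_trip_preserves_records_exactly(self, ngamo_small, tmp_path):
        obs, _ = ngamo_small
        write_observations(obs, tmp_path)
        back = read_observations(
            tmp_path / "scans.csv", tmp_path / "events.csv",
            tmp_path / "roster.csv", tmp_path / "kinship.csv",
        )
        assert back.ids == obs.ids
        assert len(back.scans) == len(obs.scans)
        assert len(back.events) == len(obs.events)
        assert back.scans[0] == obs.scans[0]
        assert back.events[:5] == obs.events[:5]
        assert np.allclose(back.kinship.values, obs.kinship.values)

    def test_error_reports_offending_line(self, tmp_path):
        (tmp_path / "roster.csv").write_text("id,sex,age_class\nA,female,adult\nB,male,adult\n")
        (tmp_path / "scans.csv").write_text("session_id,timestamp,present\ns1,2012-01-06T07:00,A|B\n")
        (tmp_path / "events.csv").write_text(
            "timestamp,initiator,recipient,behavior,accepted\n"
            "2012-01-06T07:00,A,B,play,true\n"
            "2012-01-06T07:05,B,B,play,true\n"
        )
        with pytest.raises(ObservationError, match="line 3"):
            read_observations(tmp_path / "scans.csv", tmp_path / "events.csv", tmp_path / "roster.csv")

    def test_malformed_timestamp_is_parse_error(self, tmp_path):
        (tmp_path / "roster.csv").write_text("id,sex,age_class\nA,female,adult\nB,male,adult\n")
        (tmp_path / "scans.csv").write_text("session_id,timestamp,present\ns1,yesterday-ish,A|B\n")
        (tmp_path / "events.csv").write_text("timestamp,initiator,recipient,behavior,accepted\n")
        with pytest.raises(ObservationError, match="timestamp"):
            read_observations(tmp_path / "scans.csv", tmp_path / "events.csv", tmp_path / "roster.csv")

    def test_empty_events_one_scan(self, tmp_path):
        (tmp_path / "roster.csv").write_text("id,sex,age_class\nA,female,adult\nB,male,adult\n")
        (tmp_path / "scans.csv").write_text("session_id,timestamp,present\ns1,2012-01-06T07:00,A|B\n")
        (tmp_path / "events.csv").write_text("timestamp,initiator,recipient,behavior,accepted\n")
        obs = read_observations(tmp_path / "scans.csv", tmp_path / "events.csv", tmp_path / "roster.csv")
        assert len(obs.events) == 0
        assert len(obs.scans) == 1
        # absent inferred as roster minus present
        assert obs.scans[0].absent == frozenset()

    def test_packaged_pride_fixture(self):
        from pridenet.data import ngamo_kinship, ngamo_roster

        roster = ngamo_roster()
        kin = ngamo_kinship()
        assert len(roster) == 12
        assert kin.shape == (11, 11)  # the introduced male is absent
        assert kin.loc["AS", "AS4"] == 0.5
        obs = ObservationSet(roster=roster, kinship=kin)
        full = obs.kinship_full()
        assert full.shape == (12, 12)
        assert (full.loc["MI"].drop("MI") == 0).all()


class TestDeduplicateBouts:
    def test_sub_minute_repeats_merge(self):
        assert len(deduplicate_bouts([ev(0), ev(30)])) == 1

    def test_above_gap_kept(self):
        assert len(deduplicate_bouts([ev(0), ev(61)])) == 2

    def test_streams_are_independent(self):
        events = [ev(0, "A", "B"), ev(15, "B", "A"), ev(30, "A", "B")]
        kept = deduplicate_bouts(events)
        # B->A at t=15 does not reset the A->B stream; A->B at 30 merges into t=0
        assert len(kept) == 2
        assert {e.stream for e in kept} == {("A", "B", "play"), ("B", "A", "play")}

    def test_chained_bursts_collapse_to_bout_starts(self):
        kept = deduplicate_bouts([ev(0), ev(40), ev(80), ev(150)])
        # 40 merges into the bout at 0; 80 and 150 are each >= 60s after the
        # previously retained bout start
        assert [e.timestamp for e in kept] == [T0, T0 + dt.timedelta(seconds=80),
                                               T0 + dt.timedelta(seconds=150)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            deduplicate_bouts([ev(0)], gap=dt.timedelta(seconds=-1))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seconds=st.lists(st.integers(0, 600), min_size=1, max_size=30),
        dyads=st.data(),
    )
    def test_idempotent(self, seconds, dyads):
        pairs = [("A", "B"), ("B", "A"), ("A", "C")]
        events = [
            ev(s, *dyads.draw(st.sampled_from(pairs)), behavior="greeting") for s in seconds
        ]
        once = deduplicate_bouts(events)
        assert deduplicate_bouts(once) == once


class TestSubset:
    def test_excluding_cubs_leaves_seven_adults(self, ngamo_small):
        obs, _ = ngamo_small
        reduced = subset_observations(obs, obs.cub_ids)
        assert len(reduced.roster) == 7
        assert set(reduced.ids) == {"MI", "AS", "KE", "KW", "NL", "NR", "PH"}
        assert reduced.kinship.shape == (7, 7)

    def test_empty_exclusion_is_identity(self, ngamo_small):
        obs, _ = ngamo_small
        assert subset_observations(obs, set()) is obs

    def test_event_count_drops_by_brute_force_count(self, ngamo_small):
        obs, _ = ngamo_small
        cubs = set(obs.cub_ids)
        k = sum(1 for e in obs.events if e.initiator in cubs or e.recipient in cubs)
        reduced = subset_observations(obs, cubs)
        assert len(reduced.events) == len(obs.events) - k

    def test_excluding_everyone_errors(self, ngamo_small):
        obs, _ = ngamo_small
        with pytest.raises(ObservationError, match="empty network"):
            subset_observations(obs, set(obs.ids))

    def test_subset_commutes_with_interaction_matrix(self, rng, toy_roster):
        ids = [i.id for i in toy_roster]
        events = random_events(rng, ids, 120)
        obs = ObservationSet(roster=toy_roster, events=tuple(events))
        reduced = subset_observations(obs, {"D"})
        direct = build_interaction_matrix(reduced.events, "play", reduced.ids)
        full = build_interaction_matrix(obs.events, "play", ids)
        kept = [ids.index(i) for i in reduced.ids]
        assert np.array_equal(direct.values, full.values[np.ix_(kept, kept)])


def test_data_point_accounting_sums(ngamo_small):
    obs, _ = ngamo_small
    acc = data_point_accounting(obs)
    assert acc["total"] == len(obs.scans) + len(obs.events)
    assert acc["play"] + acc["greeting"] + acc["social_licking"] == len(obs.events)
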