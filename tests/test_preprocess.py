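"""Preprocessing: minute gridding, gap interpolation, episode delimiting, chunking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pulsedyn.errors import (
    EmptyDatasetError,
    EmptyInputError,
    InputError,
    InvalidEpisodeError,
    ParameterError,
)
from pulsedyn.preprocess import (
    MinuteSeries,
    RawEventTable,
    apply_smoking_episodes,
    delimit_smoking_episode,
    interpolate_short_gaps,
    make_chunks,
    preprocess_participant,
    to_minute_grid,
)


def series_from(stress, smoking=None):
    stress = np.asarray(stress, dtype=float)
    if smoking is None:
        smoking = np.zeros(stress.size, dtype=np.int8)
    return MinuteSeries("p", np.arange(stress.size), stress, np.asarray(smoking, dtype=np.int8))


class TestToMinuteGrid:
    def test_rounds_to_nearest_minute(self):
        raw = RawEventTable("p", [(59, 0.2), (118, 0.4)], [])
        out = to_minute_grid(raw)
        # both samples land on consecutive minutes starting at the first
        assert np.allclose(out.stress, [0.2, 0.4])

    def test_collision_resolved_by_mean(self):
        raw = RawEventTable("p", [(0, 0.1), (7 * 60 - 10, 0.2), (7 * 60 + 20, 0.6)], [])
        out = to_minute_grid(raw)
        assert out.stress[7] == pytest.approx(0.4)

    def test_exact_boundary_is_identity(self):
        raw = RawEventTable("p", [(600, 0.7)], [])
        out = to_minute_grid(raw)
        assert out.stress.size == 1 and out.stress[0] == 0.7

    def test_unsampled_minutes_are_missing(self):
        raw = RawEventTable("p", [(0, 0.5), (180, 0.5)], [])
        out = to_minute_grid(raw)
        assert np.isnan(out.stress[1]) and np.isnan(out.stress[2])
        assert np.all(out.smoking == 0)

    @pytest.mark.parametrize("bad", [-0.1, 1.5, np.nan])
    def test_rejects_probability_outside_unit_interval(self, bad):
        with pytest.raises(InputError):
            to_minute_grid(RawEventTable("p", [(0, bad)], []))

    def test_rejects_empty_table(self):
        with pytest.raises(EmptyInputError):
            to_minute_grid(RawEventTable("p", [], []))


class TestInterpolateShortGaps:
    def test_linear_fill_of_two_minute_gap(self):
        out = interpolate_short_gaps(series_from([0.2, np.nan, np.nan, 0.8]))
        assert np.allclose(out.stress, [0.2, 0.4, 0.6, 0.8])

    def test_three_minute_gap_untouched(self):
        out = interpolate_short_gaps(series_from([0.2, np.nan, np.nan, np.nan, 0.8]))
        assert np.isnan(out.stress[1:4]).all()

    def test_no_gaps_is_identity(self):
        s = series_from([0.1, 0.2, 0.3])
        out = interpolate_short_gaps(s)
        assert np.array_equal(out.stress, s.stress)

    def test_edge_gaps_not_filled(self):
        out = interpolate_short_gaps(series_from([np.nan, 0.5, np.nan]))
        assert np.isnan(out.stress[0]) and np.isnan(out.stress[2])

    def test_negative_max_gap_rejected(self):
        with pytest.raises(ParameterError):
            interpolate_short_gaps(series_from([0.5]), max_gap=-1)

    @given(
        st.lists(
            st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_idempotent(self, values):
        stress = [np.nan if v is None else v for v in values]
        once = interpolate_short_gaps(series_from(stress))
        twice = interpolate_short_gaps(once)
        assert np.array_equal(once.stress, twice.stress, equal_nan=True)


class TestDelimitSmokingEpisode:
    @pytest.mark.parametrize(
        "start,puffs,end,minutes",
        [
            (0, [0, 1, 2, 3], 3, list(range(4))),
            (0, [0, 1, 2, 3, 5, 6], 6, list(range(7))),
            (10, [10, 11, 12, 13], 13, [10, 11, 12, 13]),
        ],
    )
    def test_window_extension(self, start, puffs, end, minutes):
        got_end, got_minutes = delimit_smoking_episode(start, puffs)
        assert got_end == end
        assert got_minutes == minutes

    def test_too_few_puffs_is_invalid(self):
        with pytest.raises(InvalidEpisodeError):
            delimit_smoking_episode(0, [0, 1, 2])

    def test_every_used_window_had_four_puffs(self):
        # replay the sliding-window rule on the output
        start, puffs = 0, [0, 1, 2, 3, 4, 5, 6, 8]
        end, _ = delimit_smoking_episode(start, puffs)
        arr = np.array(puffs)
        i = 0
        while True:
            lo = start + i
            count = np.sum((arr >= lo) & (arr < lo + 5))
            if count < 4:
                break
            i += 1
        qualifying_max = max(
            p for p in puffs if any(
                start + j <= p < start + j + 5 for j in range(i)
            )
        )
        assert end == qualifying_max


class TestMakeChunks:
    def test_short_runs_dropped_and_stats(self):
        stress = np.concatenate(
            [np.full(4, 0.5), [np.nan] * 3, np.full(5, 0.5), [np.nan] * 4, np.full(7, 0.5)]
        )
        ds = make_chunks(series_from(stress))
        assert ds.N_ch == 2
        assert [c.length for c in ds.chunks] == [5, 7]
        assert ds.N_l == pytest.approx(6.0)

    def test_uninterrupted_series_single_chunk(self):
        ds = make_chunks(series_from(np.full(20, 0.3)))
        assert ds.N_ch == 1 and ds.chunks[0].length == 20

    def test_all_runs_short_raises(self):
        stress = np.concatenate([np.full(3, 0.5), [np.nan] * 5, np.full(4, 0.5)])
        with pytest.raises(EmptyDatasetError):
            make_chunks(series_from(stress))

    @given(st.lists(st.booleans(), min_size=5, max_size=80), st.integers(1, 6))
    @settings(max_examples=100, derandomize=True)
    def test_partition_property(self, present, min_length):
        stress = np.where(present, 0.5, np.nan)
        series = series_from(stress)
        try:
            ds = make_chunks(series, min_length=min_length)
        except EmptyDatasetError:
            return
        covered = set()
        for c in ds.chunks:
            assert c.length >= min_length
            assert not np.isnan(c.u).any()
            minutes = set(range(c.start_minute, c.start_minute + c.length))
            assert not (covered & minutes)  # no minute in two chunks
            covered |= minutes
        # every chunk minute was a present minute
        present_minutes = {i for i, ok in enumerate(present) if ok}
        assert covered <= present_minutes


def build_toy_tables():
    """A 40-minute hand-checkable participant record.

    Gaps of 1, 2, 3 and 6 minutes; one stress collision on minute 7; two
    puff episodes.  Expected outcome (hand-derived): two retained chunks of
    lengths 20 (minutes 0-19, short gaps interpolated) and 7 (minutes
    23-29); the 4-minute tail run 36-39 is dropped.
    """
    vals = {
        0: 0.2, 1: 0.3, 2: 0.25, 3: 0.2, 4: 0.3,
        6: 0.5, 8: 0.35, 9: 0.3, 10: 0.2,
        13: 0.8, 14: 0.7, 15: 0.6, 16: 0.5, 17: 0.4, 18: 0.35, 19: 0.3,
        23: 0.3, 24: 0.4, 25: 0.5, 26: 0.6, 27: 0.5, 28: 0.4, 29: 0.3,
        36: 0.2, 37: 0.2, 38: 0.2, 39: 0.2,
    }
    stress_rows = [
        {"participant_id": "toy", "timestamp_unix_s": m * 60, "stress_probability": v}
        for m, v in sorted(vals.items())
    ]
    # collision: two samples rounding to minute 7 (0.2 and 0.6 -> mean 0.4)
    stress_rows.append(
        {"participant_id": "toy", "timestamp_unix_s": 7 * 60 - 10, "stress_probability": 0.2}
    )
    stress_rows.append(
        {"participant_id": "toy", "timestamp_unix_s": 7 * 60 + 20, "stress_probability": 0.6}
    )
    puff_rows = []
    for start, puffs in [(2, [2, 3, 4, 5]), (23, [23, 24, 25, 26, 28, 29])]:
        for pm in puffs:
            puff_rows.append(
                {
                    "participant_id": "toy",
                    "episode_start_unix_s": start * 60,
                    "puff_unix_s": pm * 60,
                }
            )
    return pd.DataFrame(stress_rows), pd.DataFrame(puff_rows)


def test_toy_pipeline_end_to_end():
    """Gaps, collision, interpolation, episodes and chunking on a hand-checked record."""
    stress_df, puffs_df = build_toy_tables()
    ds, report = preprocess_participant(stress_df, puffs_df, "toy")
    assert ds.N_ch == 2
    assert [c.length for c in ds.chunks] == [20, 7]
    assert ds.N_l == pytest.approx(13.5)
    c1, c2 = ds.chunks
    assert c1.start_minute == 0 and c2.start_minute == 23
    # collision mean and linear interpolation of the 2-minute gap (0.2 -> 0.8)
    assert c1.u[7] == pytest.approx(0.4)
    assert c1.u[11] == pytest.approx(0.4)
    assert c1.u[12] == pytest.approx(0.6)
    # 1-minute gap at minute 5 interpolated between 0.3 and 0.5
    assert c1.u[5] == pytest.approx(0.4)
    # episode 1: puffs {2,3,4,5} -> smoking minutes 2-5
    assert list(np.flatnonzero(c1.s)) == [2, 3, 4, 5]
    # episode 2: puffs {23..26,28,29} -> smoking minutes 23-29 (whole chunk)
    assert c2.s.sum() == 7
    # dropped tail run of 4 minutes reported
    assert any(d["length"] == 4 for d in report["dropped_runs"])


def test_smoking_in_gap_is_discarded_with_the_gap():
    stress = np.array([0.5, 0.5, np.nan, np.nan, np.nan, 0.5, 0.5, 0.5, 0.5, 0.5])
    series = series_from(stress)
    out = apply_smoking_episodes(series, [(1, [1, 2, 3, 4])])
    # minutes 2-4 of the episode fall in the long gap: only minute 1 marked
    assert out.smoking[1] == 1
    assert np.all(out.smoking[5:] == 0)
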