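"""Mitotic phase durations, orientation summaries and group comparisons."""

import numpy as np
import pytest
from scipy import stats

from cortexdev import (
    MitosisTrack,
    OrientationTrack,
    cleavage_angle,
    compare_groups,
    gen_mitosis_tracks,
    orientation_range,
    phase_durations,
)
from cortexdev.mitosis_timing import (
    EVENT_FIELDS,
    PHASE_NAMES,
    TrackError,
    orientation_tracks_from_csv,
    orientation_tracks_to_csv,
    tracks_from_csv,
    tracks_to_csv,
)


def track_from_times(times, cell_id="c0", group="g", frame_interval=1.1):
    return MitosisTrack(
        cell_id=cell_id,
        group=group,
        frame_interval=frame_interval,
        **dict(zip(EVENT_FIELDS, times)),
    )


class TestPhaseDurations:
    def test_successive_difference_example(self):
        d = phase_durations(track_from_times([0.0, 5.5, 9.9, 16.5, 19.8, 26.4]))
        assert d.prophase == pytest.approx(5.5)
        assert d.prometaphase == pytest.approx(4.4)
        assert d.metaphase == pytest.approx(6.6)
        assert d.anaphase == pytest.approx(3.3)
        assert d.telophase == pytest.approx(6.6)
        assert d.prometa_meta == pytest.approx(11.0)
        assert d.total == pytest.approx(26.4)

    def test_simultaneous_events_give_zero_durations(self):
        d = phase_durations(track_from_times([2.2] * 6))
        assert all(getattr(d, p) == 0.0 for p in PHASE_NAMES)
        assert d.total == 0.0

    def test_durations_invert_to_event_times(self):
        times = [1.1, 3.3, 7.7, 14.3, 16.5, 24.2]
        d = phase_durations(track_from_times(times))
        rebuilt = np.concatenate(
            [[times[0]], times[0] + np.cumsum([getattr(d, p) for p in PHASE_NAMES])]
        )
        assert np.allclose(rebuilt, times)

    def test_disordered_events_rejected(self):
        with pytest.raises(TrackError, match="after"):
            track_from_times([0.0, 9.9, 5.5, 16.5, 19.8, 26.4])

    def test_negative_time_rejected(self):
        with pytest.raises(TrackError, match="negative"):
            track_from_times([-1.1, 5.5, 9.9, 16.5, 19.8, 26.4])

    def test_off_grid_time_rejected(self):
        with pytest.raises(TrackError, match="frame grid"):
            track_from_times([0.0, 5.0, 9.9, 16.5, 19.8, 26.4])

    def test_as_dict_fields(self):
        d = phase_durations(track_from_times([0.0, 5.5, 9.9, 16.5, 19.8, 26.4]))
        out = d.as_dict()
        assert set(out) == set(PHASE_NAMES) | {"prometa_meta", "total"}


class TestCompareGroups:
    def test_group_against_itself_not_significant(self):
        vals = [5.5, 6.6, 7.7, 8.8, 9.9]
        res = compare_groups({"a": vals, "b": list(vals)})
        assert res.test_name == "mann-whitney"
        assert res.p_value > 0.9
        assert not res.significant

    def test_two_group_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            a = rng.uniform(5, 15, 4)
            b = rng.uniform(5, 15, 4) + rng.uniform(0, 4)
            res = compare_groups({"a": a, "b": b})
            _, p_exact = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact"
            )
            assert res.p_value == pytest.approx(p_exact), f"trial {trial}"

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = compare_groups({"a": [1.1, 2.2, 3.3], "b": [4.4, 5.5, 6.6], "tiny": [7.7]})
        assert res.excluded_groups == ["tiny"]
        assert res.test_name == "mann-whitney"

    def test_fewer_than_two_usable_groups_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="two groups"):
                compare_groups({"a": [1.1, 2.2, 3.3], "b": [4.4]})

    def test_three_groups_dunn_flags_only_shifted_pair(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 1.5, 40)
        groups = {
            "a": base,
            "b": rng.normal(10, 1.5, 40),
            "c": rng.normal(16, 1.5, 40),
        }
        res = compare_groups(groups, phase="metaphase")
        assert res.test_name == "kruskal-wallis+dunn"
        assert res.significant
        pw = res.pairwise.set_index(["group1", "group2"])["significant"]
        assert not pw[("a", "b")]
        assert pw[("a", "c")]
        assert pw[("b", "c")]

    def test_bonferroni_never_below_raw_p(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(10, 2, 20) for g in ("a", "b", "c")}
        raw = compare_groups(groups).pairwise
        adj = compare_groups(groups, adjust="bonferroni").pairwise
        assert (adj["p_adjusted"] >= raw["p"] - 1e-12).all()
        assert (adj["p_adjusted"] <= 1.0).all()

    def test_holm_between_raw_and_bonferroni(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(10, 2, 15) + s for g, s in (("a", 0), ("b", 1), ("c", 3))}
        raw = compare_groups(groups).pairwise["p"]
        holm = compare_groups(groups, adjust="holm").pairwise["p_adjusted"]
        bonf = compare_groups(groups, adjust="bonferroni").pairwise["p_adjusted"]
        assert (holm >= raw - 1e-12).all()
        assert (holm <= bonf + 1e-12).all()

    def test_unknown_adjustment_rejected(self):
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(10, 2, 10) for g in ("a", "b", "c")}
        with pytest.raises(ValueError, match="adjustment"):
            compare_groups(groups, adjust="fdr")

    def test_group_stats_reported(self):
        res = compare_groups({"a": [1.1, 2.2, 3.3], "b": [4.4, 5.5, 6.6]})
        gs = res.group_stats.set_index("group")
        assert gs.loc["a", "n"] == 3
        assert gs.loc["a", "median"] == pytest.approx(2.2)
        assert gs.loc["b", "mean"] == pytest.approx(5.5)

    def test_json_report_round_trips_through_dict(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(10, 2, 12) for g in ("a", "b", "c")}
        res = compare_groups(groups, phase="prometaphase")
        d = res.to_json_dict()
        assert d["phase"] == "prometaphase"
        assert len(d["groups"]) == 3
        assert len(d["pairwise"]) == 3


def orientation_track(times, angles, plate=0.0, ana=None, cell_id="o0"):
    times = np.asarray(times, dtype=float)
    if ana is None:
        ana = times.max()
    return OrientationTrack(
        cell_id=cell_id,
        times=times,
        angles=np.asarray(angles, dtype=float),
        t_plate_formed=plate,
        t_anaphase_onset=ana,
    )


class TestOrientationRange:
    def test_constant_angle_zero_range(self):
        t = orientation_track([0, 1.1, 2.2, 3.3], [45] * 4)
        assert orientation_range(t) == 0.0

    def test_known_spread(self):
        t = orientation_track([0, 1.1, 2.2], [60, 88, 75])
        assert orientation_range(t) == pytest.approx(28.0)

    def test_only_window_samples_counted(self):
        # the 5-degree sample before plate formation must not widen the range
        t = orientation_track([0, 1.1, 2.2, 3.3], [5, 50, 55, 60], plate=1.1, ana=3.3)
        assert orientation_range(t) == pytest.approx(10.0)

    def test_empty_window_rejected(self):
        t = OrientationTrack(
            cell_id="o1",
            times=np.array([0.0, 5.5]),
            angles=np.array([40.0, 50.0]),
            t_plate_formed=1.1,
            t_anaphase_onset=2.2,
        )
        with pytest.raises(TrackError, match="no samples"):
            orientation_range(t)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(TrackError, match="angles"):
            orientation_track([0, 1.1], [45, 95])


class TestCleavageAngle:
    def test_exact_sample_at_offset(self):
        t = orientation_track([0, 1.1, 2.2, 3.3, 4.4], [40, 42, 44, 46, 48], ana=1.1)
        # anaphase onset 1.1 + offset 2.2 = 3.3, an exact sample time
        assert cleavage_angle(t, offset=2.2) == 46.0

    def test_tie_resolves_to_earlier_sample(self):
        # target 2.0 is equidistant from samples at 1.5 and 2.5
        t = OrientationTrack(
            cell_id="o2",
            times=np.array([0.0, 1.5, 2.5]),
            angles=np.array([10.0, 20.0, 30.0]),
            t_plate_formed=0.0,
            t_anaphase_onset=0.0,
        )
        assert cleavage_angle(t, offset=2.0) == 20.0

    def test_drifting_plate_read_after_drift(self):
        # 1 degree/min drift from 80 degrees: at onset+2.2 min expect 82.2
        times = np.arange(0, 6.6, 1.1)
        angles = 80.0 + times
        t = orientation_track(times, angles, ana=0.0)
        assert cleavage_angle(t, offset=2.2) == pytest.approx(82.2)

    def test_track_ending_too_early_rejected(self):
        t = orientation_track([0, 1.1], [45, 46], ana=1.1)
        with pytest.raises(TrackError, match="past anaphase"):
            cleavage_angle(t, offset=2.2)


class TestCsvRoundTrips:
    def test_mitosis_tracks_round_trip(self, tmp_path):
        means = dict(zip(PHASE_NAMES, (2.0, 4.0, 5.0, 2.0, 4.0)))
        sds = dict.fromkeys(PHASE_NAMES, 0.5)
        tracks = gen_mitosis_tracks(groups=[("human", means, sds, 6)], seed=0)
        path = tmp_path / "tracks.csv"
        tracks_to_csv(tracks, path)
        back = tracks_from_csv(path)
        assert len(back) == len(tracks)
        for a, b in zip(tracks, back):
            assert a.cell_id == b.cell_id and a.group == b.group
            assert np.allclose(a.event_times, b.event_times)

    def test_orientation_tracks_round_trip(self, tmp_path):
        tracks = [
            orientation_track([0, 1.1, 2.2], [30, 40, 50], cell_id="a"),
            orientation_track([0, 1.1, 2.2, 3.3], [60, 62, 64, 66], cell_id="b"),
        ]
        path = tmp_path / "orient.csv"
        orientation_tracks_to_csv(tracks, path)
        back = orientation_tracks_from_csv(path)
        assert [t.cell_id for t in back] == ["a", "b"]
        for a, b in zip(tracks, back):
            assert np.allclose(a.times, b.times)
            assert np.allclose(a.angles, b.angles)
            assert a.t_anaphase_onset == b.t_anaphase_onset
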