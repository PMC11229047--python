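"""Scanpath metrics: entropy, anisotropy, search measures, aggregation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazesweep import (
    FixationEvent,
    GazeRecording,
    SaccadeEvent,
    TrialMetrics,
    aggregate_participant,
    angle_differences,
    antipersistent_fraction,
    assign_aois,
    compute_trial_metrics,
    default_room_layout,
    intersaccadic_angles,
    saccadic_angle,
    search_order_met,
    time_to_first_target,
    transition_entropy,
    transition_matrix,
)
from gazesweep.metrics import TransitionMatrix


def brute_force_entropy(seq):
    """Direct evaluation: collapse repeats, tabulate counts, sum the
    conditional-entropy formula term by term."""
    s = [a for a in seq if a is not None]
    s = [a for k, a in enumerate(s) if k == 0 or a != s[k - 1]]
    pairs = list(zip(s[:-1], s[1:]))
    if len(pairs) < 2:
        return 0.0
    total = len(pairs)
    h = 0.0
    for i in set(a for a, _ in pairs):
        row = [(a, b) for a, b in pairs if a == i]
        p_i = len(row) / total
        inner = 0.0
        for j in set(b for _, b in row):
            p_ji = sum(1 for _, b in row if b == j) / len(row)
            inner += p_ji * math.log2(p_ji)
        h += p_i * -inner
    return h


class TestAssignAois:
    def test_interior_point_gets_segment_id(self, layout):
        fx = [FixationEvent(0, 0.2, -160.0, 0.0)]  # inside segment 1
        assert assign_aois(fx, layout)[0].aoi_id == 1

    def test_point_outside_all_polygons_is_none(self, layout):
        fx = [FixationEvent(0, 0.2, 0.0, 50.0)]
        assert assign_aois(fx, layout)[0].aoi_id is None

    def test_shared_boundary_goes_to_lower_numbered_aoi(self, layout):
        fx = [FixationEvent(0, 0.2, -150.0, 0.0)]  # boundary of segments 1|2
        assert assign_aois(fx, layout)[0].aoi_id == 1

    def test_targets_take_precedence_when_requested(self, layout):
        tgt = layout.targets[0].polygon.centroid
        fx = [FixationEvent(0, 0.2, tgt.x, tgt.y)]
        assert assign_aois(fx, layout)[0].aoi_id in layout.segment_ids
        assert str(assign_aois(fx, layout, targets_first=True)[0].aoi_id).startswith("target")


class TestTransitionEntropy:
    def test_deterministic_cycle_is_zero_bits(self):
        assert transition_entropy([1, 2, 3] * 10, n_aois=3) == 0.0

    def test_uniform_conditionals_over_12_aois_hit_log2_11(self):
        # walk every ordered AOI pair exactly once (Eulerian circuit on
        # the complete digraph): p(j|i) uniform over the 11 others
        import networkx as nx

        g = nx.complete_graph(12, create_using=nx.DiGraph)
        seq = [u + 1 for u, _ in nx.eulerian_circuit(g, source=0)]
        seq.append(seq[0])
        assert transition_entropy(seq, n_aois=12) == pytest.approx(math.log2(11), abs=1e-9)

    def test_hand_computed_count_table(self):
        tm = TransitionMatrix(labels=["A", "B", "C"],
                              counts=[[0, 2, 2], [4, 0, 0], [0, 0, 0]])
        # p(A)=p(B)=1/2; H(row A)=1 bit, H(row B)=0
        assert tm.entropy() == pytest.approx(0.5)

    def test_matches_brute_force_on_short_sequences(self):
        for n in range(1, 7):
            for seq in itertools.product("XYZ", repeat=n):
                assert transition_entropy(list(seq)) == pytest.approx(
                    brute_force_entropy(seq), abs=1e-12)

    def test_repeats_and_unlabelled_fixations_are_collapsed(self):
        assert transition_entropy([1, 1, None, 2, 2, 3, 3], n_aois=3) == \
            transition_entropy([1, 2, 3], n_aois=3)

    @given(st.lists(st.integers(1, 5), min_size=0, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_entropy_bounds(self, seq):
        h = transition_entropy(seq, n_aois=5)
        assert 0.0 <= h <= math.log2(4) + 1e-12

    def test_fewer_than_two_transitions_is_zero(self):
        assert transition_entropy([1], n_aois=3) == 0.0
        assert transition_entropy([1, 2], n_aois=3) == 0.0

    def test_matrix_probabilities_consistent(self):
        tm = transition_matrix([1, 2, 1, 3, 1, 2], n_aois=3)
        assert tm.p_i.sum() == pytest.approx(1.0)
        rows = tm.counts.sum(axis=1)
        for r, row_p in zip(rows, tm.p_cond):
            assert row_p.sum() == pytest.approx(1.0 if r else 0.0)
        assert np.all(np.diag(tm.counts) == 0)


class TestSaccadicAngles:
    @pytest.mark.parametrize("rx, ry, expected", [
        (1.0, 0.0, 0.0),      # rightward
        (-1.0, 0.0, 180.0),   # leftward
        (0.0, 1.0, 90.0),     # upward
        (0.0, -1.0, -90.0),
        (1.0, 1.0, 45.0),
    ])
    def test_quadrants(self, rx, ry, expected):
        assert saccadic_angle(rx, ry) == pytest.approx(expected)

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            saccadic_angle(0.0, 0.0)

    @pytest.mark.parametrize("angles, expected", [
        ([0.0, 0.0, 0.0], [0.0, 0.0]),
        ([170.0, -170.0], [20.0]),   # wraps, not 340
        ([0.0, 180.0], [180.0]),     # boundary maps to +180
    ])
    def test_angle_differences_wrap(self, angles, expected):
        assert angle_differences(angles) == pytest.approx(expected)

    def test_intersaccadic_from_events(self):
        sacs = [SaccadeEvent(0.0, 0.05, 1.0, 0.0),
                SaccadeEvent(0.3, 0.35, 0.0, 1.0),
                SaccadeEvent(0.6, 0.65, -1.0, 0.0)]
        assert intersaccadic_angles(sacs) == pytest.approx([90.0, 90.0])
        assert intersaccadic_angles(sacs[:1]) == []


class TestAntipersistentFraction:
    @pytest.mark.parametrize("theta_d, expected", [
        ([0.0, 10.0, -30.0], 0.0),
        ([180.0, 179.0, -120.0], 100.0),
        ([90.0], 0.0),            # inclusive boundary counts persistent
        ([90.5], 100.0),
        ([], None),
    ])
    def test_classification(self, theta_d, expected):
        assert antipersistent_fraction(theta_d) == expected

    @given(st.lists(st.integers(-719, 719).map(lambda k: k / 2.0),
                    min_size=2, max_size=30),
           st.integers(-719, 719).map(lambda k: k / 2.0))
    @settings(deadline=None, max_examples=60)
    def test_rotation_and_wrap_invariance(self, thetas, rot):
        base = antipersistent_fraction(angle_differences(thetas))
        rotated = antipersistent_fraction(angle_differences([t + rot for t in thetas]))
        wrapped = antipersistent_fraction(angle_differences([t + 360.0 for t in thetas]))
        assert rotated == base
        assert wrapped == base


class TestSearchMeasures:
    def test_time_to_first_target(self, layout):
        tgt = layout.targets[0].polygon.centroid
        n = 600
        t = np.arange(n) / 120.0
        az = np.full(n, -170.0)
        el = np.zeros(n)
        hit = np.searchsorted(t, 2.4)
        az[hit:] = tgt.x
        el[hit:] = tgt.y
        rec = GazeRecording(t=t, az=az, el=el, valid=np.ones(n, bool))
        assert time_to_first_target(rec, layout, entry_time=0.0) == pytest.approx(
            t[hit], abs=1e-9)

    def test_no_target_intersection_is_none(self, layout):
        n = 120
        rec = GazeRecording(t=np.arange(n) / 120.0, az=np.full(n, -170.0),
                            el=np.zeros(n), valid=np.ones(n, bool))
        assert time_to_first_target(rec, layout, entry_time=0.0) is None

    def test_gaze_in_target_at_entry_gives_zero(self, layout):
        tgt = layout.targets[0].polygon.centroid
        n = 120
        rec = GazeRecording(t=np.arange(n) / 120.0, az=np.full(n, tgt.x),
                            el=np.full(n, tgt.y), valid=np.ones(n, bool))
        assert time_to_first_target(rec, layout, entry_time=0.0) == 0.0

    def test_entry_time_outside_span_rejected(self, layout):
        n = 120
        rec = GazeRecording(t=np.arange(n) / 120.0, az=np.zeros(n),
                            el=np.zeros(n), valid=np.ones(n, bool))
        with pytest.raises(ValueError, match="entry_time"):
            time_to_first_target(rec, layout, entry_time=5.0)

    def test_search_order(self, layout):
        # layout tags near_corner = {1, 12}, back_wall = {6, 7}
        assert search_order_met([1, 3, 6], layout) is True
        assert search_order_met([6, 1, 3], layout) is False
        assert search_order_met([3, 4, 5], layout) is False  # neither fixated
        assert search_order_met([12, 2], layout) is True     # corner, no back wall

    def test_missing_role_tags_rejected(self, layout):
        from gazesweep.aoi import AOILayout

        bare = AOILayout(aois=layout.aois)
        with pytest.raises(ValueError, match="near_corner"):
            search_order_met([1, 6], bare)


class TestTrialMetricsAndAggregation:
    def test_search_rate_is_count_over_mean_duration(self, layout):
        fx = [FixationEvent(k * 0.3, k * 0.3 + 0.25, -160.0, 0.0) for k in range(10)]
        tm = compute_trial_metrics(fx, [], layout)
        assert tm.n_fixations == 10
        assert tm.mean_fixation_duration == pytest.approx(0.25)
        assert tm.search_rate == pytest.approx(40.0)

    def test_no_fixations_gives_none_fields(self, layout):
        tm = compute_trial_metrics([], [], layout)
        assert tm.mean_fixation_duration is None
        assert tm.search_rate is None
        assert tm.entropy == 0.0

    def test_aggregate_search_order_as_percent(self):
        trials = [TrialMetrics(search_order_met=(k < 15)) for k in range(20)]
        assert aggregate_participant(trials)["search_order_met"] == pytest.approx(75.0)

    def test_aggregate_single_trial_identity(self):
        tm = TrialMetrics(mean_fixation_duration=0.3, n_fixations=10,
                          search_rate=33.3, entropy=1.5, pct_antipersistent=40.0)
        agg = aggregate_participant([tm])
        assert agg["mean_fixation_duration"] == pytest.approx(0.3)
        assert agg["entropy"] == pytest.approx(1.5)

    def test_aggregate_means_and_all_none(self):
        trials = [TrialMetrics(mean_fixation_duration=d) for d in (0.2, 0.3, 0.4)]
        agg = aggregate_participant(trials)
        assert agg["mean_fixation_duration"] == pytest.approx(0.3)
        assert agg["pct_antipersistent"] is None
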