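"""Pivot detection, wave labeling and wave-rule validation."""

import pytest
from hypothesis import given, strategies as st

from epiwave import (
    Pivot,
    WaveCount,
    WaveNode,
    detect_pivots,
    generate_elliott_epidemic,
    label_waves,
    moving_average,
    plan_impulse_correction,
    plan_in_progress,
    plan_textbook5,
    validate_wave_count,
)
from epiwave.wave_engine import CORRECTIVE, IMPULSE, role_sequence
from conftest import make_series


def unsmoothed(values):
    return moving_average(make_series(values), window=1)


class TestDetectPivots:
    def test_monotone_series_yields_endpoints_only(self):
        pivots = detect_pivots(unsmoothed([1.0, 2.0, 3.0, 4.0, 5.0]), 0.3)
        assert [(p.index, p.polarity) for p in pivots] == [(0, "trough"), (4, "peak")]

    def test_triangle_yields_three_pivots(self):
        pivots = detect_pivots(unsmoothed([1.0, 5.0, 1.0]), 0.5)
        assert [(p.index, p.polarity) for p in pivots] == [
            (0, "trough"), (1, "peak"), (2, "trough"),
        ]

    def test_small_oscillation_is_filtered(self):
        values = [10.0, 11.0] * 5
        pivots = detect_pivots(unsmoothed(values), 0.5)
        assert [p.index for p in pivots] == [0, len(values) - 1]

    def test_pivot_values_come_from_smoothed(self):
        series = unsmoothed([1.0, 5.0, 1.0])
        for pivot in detect_pivots(series, 0.5):
            assert pivot.value == series.smoothed[pivot.index]

    def test_requires_smoothed(self):
        with pytest.raises(ValueError, match="smoothed"):
            detect_pivots(make_series([1.0, 2.0, 3.0]), 0.3)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_reversal_fraction_domain(self, fraction):
        with pytest.raises(ValueError):
            detect_pivots(unsmoothed([1.0, 2.0, 3.0]), fraction)

    @given(st.lists(st.floats(0.1, 1e6), min_size=3, max_size=120))
    def test_polarities_alternate_and_endpoints_present(self, values):
        pivots = detect_pivots(unsmoothed(values), 0.3)
        assert pivots[0].index == 0 and pivots[-1].index == len(values) - 1
        for prev, cur in zip(pivots, pivots[1:]):
            assert prev.index < cur.index
            assert prev.polarity != cur.polarity

    @given(
        st.lists(st.floats(0.1, 1e4), min_size=3, max_size=60),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, values, factor):
        base = detect_pivots(unsmoothed(values), 0.3)
        scaled = detect_pivots(unsmoothed([v * factor for v in values]), 0.3)
        assert [p.index for p in base] == [p.index for p in scaled]


def alternating_pivots(values, first="trough"):
    polarities = ["trough", "peak"] if first == "trough" else ["peak", "trough"]
    return [
        Pivot(index=k, value=float(v), polarity=polarities[k % 2])
        for k, v in enumerate(values)
    ]


class TestLabelWaves:
    def test_textbook_five_wave_rise(self):
        series, truth = generate_elliott_epidemic(plan_textbook5())
        pivots = detect_pivots(moving_average(series, 1), 0.3)
        count = label_waves(pivots, max_degree=1)
        top = count.nodes
        assert len(top) == 1 and top[0].role == IMPULSE and top[0].complete
        assert [c.role for c in top[0].children] == [
            IMPULSE, CORRECTIVE, IMPULSE, CORRECTIVE, IMPULSE,
        ]
        assert [c.label for c in top[0].children] == ["i", "ii", "iii", "iv", "v"]
        assert count.violations == []
        assert count.score < 1000  # no hard-rule penalties

    def test_single_upswing_is_in_progress_wave_one(self):
        count = label_waves(alternating_pivots([10.0, 100.0]), max_degree=1)
        assert len(count.nodes) == 1
        node = count.nodes[0]
        assert node.role == IMPULSE and node.label == "1"
        assert count.in_progress

    def test_full_retrace_prefers_corrective_reading(self):
        # up-down-up where the down-swing breaks below the first swing's
        # origin: impulse 1-2-3 would violate R1, so a-b-c must win
        pivots = alternating_pivots([10.0, 110.0, 5.0, 60.0])
        count = label_waves(pivots, max_degree=1)
        assert count.nodes[0].role == CORRECTIVE
        assert count.score < 1000

    def test_rejects_single_pivot(self):
        with pytest.raises(ValueError):
            label_waves(alternating_pivots([10.0]), max_degree=1)

    def test_rejects_non_alternating(self):
        bad = [
            Pivot(index=0, value=1.0, polarity="trough"),
            Pivot(index=1, value=2.0, polarity="trough"),
        ]
        with pytest.raises(ValueError, match="alternate"):
            label_waves(bad, max_degree=1)

    def test_completed_nodes_validate_when_score_is_soft(self):
        series, _ = generate_elliott_epidemic(plan_impulse_correction())
        pivots = detect_pivots(moving_average(series, 1), 0.3)
        count = label_waves(pivots, max_degree=1)
        assert count.score < 1000
        assert validate_wave_count(count) == []

    def test_trailing_wave_marked_in_progress(self):
        series, truth = generate_elliott_epidemic(plan_in_progress())
        pivots = detect_pivots(moving_average(series, 1), 0.3)
        count = label_waves(pivots, max_degree=1)
        assert count.in_progress
        assert [n.role for n in count.nodes] == [n.role for n in truth.nodes]


def impulse_count(values, scale="linear"):
    """One degree-1 impulse over six alternating pivots."""
    pivots = alternating_pivots(values)
    children = [
        WaveNode(degree=0, role=r, label="", start=k, end=k + 1)
        for k, r in enumerate([IMPULSE, CORRECTIVE, IMPULSE, CORRECTIVE, IMPULSE])
    ]
    node = WaveNode(degree=1, role=IMPULSE, label="1", start=0, end=5, children=children)
    return WaveCount(nodes=[node], pivots=pivots, scale=scale)


class TestValidateWaveCount:
    def test_synthetic_ground_truth_is_clean(self):
        _, truth = generate_elliott_epidemic(plan_textbook5())
        assert validate_wave_count(truth) == []

    def test_deep_wave_two_retrace_raises_r1(self):
        # wave 2 ends at 8, below wave 1's start at 10
        count = impulse_count([10.0, 100.0, 8.0, 200.0, 150.0, 300.0])
        assert [v.rule for v in validate_wave_count(count)] == ["R1"]

    def test_shortest_wave_three_raises_r2(self):
        # amplitudes w1=10, w3=4, w5=8 on the linear scale
        count = impulse_count([0.0, 10.0, 8.0, 12.0, 11.0, 19.0], scale="linear")
        assert [v.rule for v in validate_wave_count(count)] == ["R2"]

    def test_wave_four_overlap_raises_r3(self):
        # wave 4 bottoms at 9, inside wave 1's 0-10 territory
        count = impulse_count([0.0, 10.0, 5.0, 20.0, 9.0, 25.0], scale="linear")
        assert [v.rule for v in validate_wave_count(count)] == ["R3"]

    def test_wrong_child_count_raises_grammar_violation(self):
        pivots = alternating_pivots([10.0, 100.0, 50.0, 200.0])
        children = [
            WaveNode(degree=0, role=r, label="", start=k, end=k + 1)
            for k, r in enumerate([IMPULSE, CORRECTIVE, IMPULSE])
        ]
        node = WaveNode(degree=1, role=IMPULSE, label="1", start=0, end=3, children=children)
        count = WaveCount(nodes=[node], pivots=pivots)
        assert "G1" in [v.rule for v in validate_wave_count(count)]

    def test_malformed_tree_raises_with_path(self):
        pivots = alternating_pivots([10.0, 100.0, 50.0])
        child = WaveNode(degree=0, role=IMPULSE, label="", start=0, end=1)
        node = WaveNode(degree=2, role=IMPULSE, label="1", start=0, end=1, children=[child])
        count = WaveCount(nodes=[node], pivots=pivots)
        with pytest.raises(ValueError, match=r"nodes\[0\]"):
            validate_wave_count(count)


class TestRoleSequence:
    def test_collects_degree_one_roles_in_order(self):
        _, truth = generate_elliott_epidemic(plan_impulse_correction())
        assert role_sequence(truth, 1) == [IMPULSE, CORRECTIVE]
        assert role_sequence(truth, 0) == [
            IMPULSE, CORRECTIVE, IMPULSE, CORRECTIVE, IMPULSE,
            IMPULSE, CORRECTIVE, IMPULSE,
        ]
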