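"""Designs, stimuli, subjects and trial scoring."""

import numpy as np
import pytest

from taskbrain.experiment import (
    BLOCK_S,
    TRIAL_S,
    TrialOutcome,
    build_dms_design,
    compute_performance,
    generate_subject,
    make_stimulus,
    score_trial,
)
from taskbrain.templates import SHAPE_LIBRARY, default_weight_set


class TestDesign:
    def test_default_design_timing(self):
        design = build_dms_design(rng=np.random.default_rng(0))
        assert len(design.trials) == 36
        assert design.total_s == pytest.approx(198.0)
        assert design.n_blocks == 12

    def test_phase_arithmetic(self):
        assert TRIAL_S == pytest.approx(1.0 + 1.5 + 1.0 + 2.0)
        assert BLOCK_S == pytest.approx(3 * 5.5)

    def test_empty_design(self):
        design = build_dms_design(n_blocks=0, rng=np.random.default_rng(0))
        assert design.trials == []
        assert design.total_s == 0.0

    def test_blocks_alternate_and_attention_schedule(self):
        design = build_dms_design(rng=np.random.default_rng(1))
        onsets = design.block_onsets()
        assert [c for _, c in onsets] == ["DMS", "CTL"] * 6
        dms_atts = sorted({t.attention for t in design.trials if t.condition == "DMS"})
        np.testing.assert_allclose(dms_atts, np.linspace(0.24, 0.34, 6))
        assert all(t.attention == 0.05 for t in design.trials if t.condition == "CTL")

    def test_match_sequence_per_dms_block(self):
        design = build_dms_design(rng=np.random.default_rng(2))
        dms = [t for t in design.trials if t.condition == "DMS"]
        assert [t.match for t in dms[:3]] == [True, False, True]
        for t in dms:
            assert (t.s1.shape_id == t.s2.shape_id) == t.match

    def test_ctl_trials_use_degraded_stimuli(self):
        design = build_dms_design(rng=np.random.default_rng(3))
        for t in design.trials:
            if t.condition == "CTL":
                assert t.s1.degraded and t.s2.degraded
            else:
                assert not t.s1.degraded and not t.s2.degraded

    def test_bad_attention_range_rejected(self):
        with pytest.raises(ValueError):
            build_dms_design(attention_range=(0.0, 0.3))


class TestStimuli:
    def test_blank_shape_is_all_zero(self):
        stim = make_stimulus("blank")
        assert stim.n_active == 0

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            make_stimulus("nonagon")

    def test_degradation_retains_about_half(self):
        intact = make_stimulus("aitch")
        rng = np.random.default_rng(0)
        kept = [
            make_stimulus("aitch", degraded=True, rng=rng, retention=0.5).n_active
            for _ in range(200)
        ]
        assert np.mean(kept) == pytest.approx(0.5 * intact.n_active, rel=0.1)
        assert all(k <= intact.n_active for k in kept)

    def test_channels_are_orientation_specific(self):
        gh = make_stimulus("bars")  # horizontal strokes only
        assert gh.grid_h.sum() > 0 and gh.grid_v.sum() == 0
        gv = make_stimulus("rails")  # vertical strokes only
        assert gv.grid_v.sum() > 0 and gv.grid_h.sum() == 0

    def test_library_has_enough_distinct_shapes(self):
        real = [s for s in SHAPE_LIBRARY if s != "blank"]
        assert len(real) >= 8


class TestSubjects:
    def test_multipliers_within_bounds(self):
        base = default_weight_set()
        rng = np.random.default_rng(0)
        for _ in range(100):
            subj = generate_subject(base, rng)
            assert all(0.95 <= v <= 1.0 for v in subj.multipliers.values())

    def test_same_seed_reproduces_subject(self):
        base = default_weight_set()
        s1 = generate_subject(base, np.random.default_rng(7))
        s2 = generate_subject(base, np.random.default_rng(7))
        assert s1.multipliers == s2.multipliers

    def test_feedback_templates_untouched(self):
        base = default_weight_set()
        subj = generate_subject(base, np.random.default_rng(1))
        scaled = base.scaled(subj.multipliers)
        for t0, t1 in zip(base.templates, scaled.templates):
            if not t0.feedforward:
                assert np.array_equal(t0.matrix, t1.matrix)
            else:
                np.testing.assert_allclose(
                    t1.matrix, t0.matrix * subj.multipliers[t0.key]
                )

    def test_only_feedforward_keys_accepted(self):
        base = default_weight_set()
        with pytest.raises(KeyError):
            base.scaled({"D2->IT:EE": 0.97})


class TestScoring:
    def _trace(self, peaks, n_steps=100):
        tr = np.zeros((n_steps, 81))
        for unit, value in peaks.items():
            tr[50, unit] = value
        return tr

    def test_two_units_above_threshold_is_response(self):
        tr = self._trace({0: 0.8, 1: 0.8})
        out = score_trial(tr, (0, 100), match=True)
        assert out.responded and out.correct
        assert out.n_FR_units_above_threshold == 2

    def test_single_unit_is_not_a_response(self):
        tr = self._trace({0: 0.9})
        out = score_trial(tr, (0, 100), match=True)
        assert not out.responded
        assert out.correct is False

    def test_threshold_is_strict(self):
        tr = self._trace({0: 0.70, 1: 0.70})
        out = score_trial(tr, (0, 100), match=True)
        assert not out.responded

    def test_mismatch_nonresponse_is_correct(self):
        tr = self._trace({})
        out = score_trial(tr, (0, 100), match=False)
        assert out.correct is True

    def test_window_restricts_detection(self):
        tr = self._trace({0: 0.9, 1: 0.9})  # peak at step 50
        assert not score_trial(tr, (60, 100), match=True).responded

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            score_trial(np.zeros((10, 81)), (5, 5))


class TestPerformance:
    def test_fourteen_of_eighteen_is_77_8(self):
        outs = [
            TrialOutcome("DMS", True, 3, i < 14) for i in range(18)
        ]
        assert compute_performance(outs) == pytest.approx(77.8, abs=0.05)

    def test_zero_correct_is_zero(self):
        outs = [TrialOutcome("DMS", False, 0, False) for _ in range(18)]
        assert compute_performance(outs) == 0.0

    def test_matches_brute_count(self):
        rng = np.random.default_rng(0)
        outs = [
            TrialOutcome("DMS", True, 2, bool(rng.integers(2))) for _ in range(25)
        ] + [TrialOutcome("CTL", False, 0, None) for _ in range(5)]
        expected = 100.0 * sum(o.correct for o in outs if o.condition == "DMS") / 25
        assert compute_performance(outs) == pytest.approx(expected)

    def test_no_dms_trials_rejected(self):
        with pytest.raises(ValueError):
            compute_performance([TrialOutcome("CTL", False, 0, None)])
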