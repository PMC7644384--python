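import numpy as np
import pytest

import penlaws as pl
from penlaws.errors import MismatchError, SegmentationError

from conftest import make_trial


def bumpy_word(n_letters=4, pts_per_bump=50, dip=-5.0, height=30.0):
    """Synthetic cursive word: letter arches joined by valleys below baseline."""
    xs, ys = [], []
    x0 = 0.0
    for k in range(n_letters):
        u = np.linspace(0, 1, pts_per_bump, endpoint=False)
        xs.append(x0 + 20.0 * u)
        ys.append(height * np.sin(np.pi * u))
        x0 += 20.0
        if k < n_letters - 1:
            u = np.linspace(0, 1, pts_per_bump // 2, endpoint=False)
            xs.append(x0 + 6.0 * u)
            ys.append(dip * np.sin(np.pi * u))
            x0 += 6.0
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.arange(len(x)) * 0.02
    return make_trial(t, x, y, item="word_mele")


class TestSegmentWord:
    def test_transitions_at_construction_valleys(self):
        trial = bumpy_word()
        bounds = pl.segment_word(trial, n_letters=4)
        assert len(bounds.intervals) == 4
        # transitions must sit in the dip regions (y < 0)
        for (_, b) in bounds.intervals[:-1]:
            assert trial.y[b] < 0

    def test_single_letter_is_whole_trace(self):
        trial = bumpy_word(2)
        bounds = pl.segment_word(trial, n_letters=1)
        assert bounds.intervals == [(0, len(trial) - 1)]

    def test_too_few_minima_raises(self):
        trial = bumpy_word(2)
        with pytest.raises(SegmentationError):
            pl.segment_word(trial, n_letters=6)

    def test_manual_boundaries_override(self):
        trial = bumpy_word()
        trial.manual_boundaries = [60, 120, 180]
        bounds = pl.segment_word(trial, n_letters=4)
        assert [b for _, b in bounds.intervals[:-1]] == [60, 120, 180]

    def test_generated_word_transitions_near_truth(self, noiseless_profile):
        trial = pl.generate_copy_trial(noiseless_profile, "word_mele",
                                       "spontaneous", seed=7)
        bounds = pl.segment_word(trial, n_letters=4)
        x, y = trial.x, trial.y
        s = np.concatenate(([0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))))
        total = s[-1]
        found = np.array([s[b] / total for _, b in bounds.intervals[:-1]])
        truth = np.asarray(trial.truth["boundary_arc_fractions"])
        np.testing.assert_allclose(found, truth, atol=0.02)


class TestSegmentSequence:
    def test_three_strokes_three_intervals(self, noiseless_profile):
        trial = pl.generate_copy_trial(noiseless_profile, "sequence",
                                       "spontaneous", seed=1)
        bounds = pl.segment_sequence(trial, expected=3)
        assert len(bounds.intervals) == 3
        # boundaries at pen lifts: intervals contain only pen-down samples
        for a, b in bounds.intervals:
            assert trial.pen_down[a:b + 1].all()

    def test_stroke_count_mismatch(self):
        trial = make_trial(np.arange(10) * 0.02, np.arange(10), np.zeros(10))
        with pytest.raises(MismatchError, match="1 strokes"):
            pl.segment_sequence(trial, expected=3)

    def test_durations_match_generator_schedule(self, noiseless_profile):
        trial = pl.generate_copy_trial(noiseless_profile, "sequence",
                                       "spontaneous", seed=2)
        bounds = pl.segment_sequence(trial, expected=3)
        durations = [trial.t[b] - trial.t[a] for a, b in bounds.intervals]
        T = trial.truth["pen_down_duration"]
        programmed = np.asarray(trial.truth["fractions"]) * T
        np.testing.assert_allclose(durations, programmed, atol=0.02 + 1e-9)


class TestFractionTimes:
    def _seq_trial(self, durations, gap=0.5):
        t_parts, pen_parts = [], []
        t0 = 0.0
        for k, d in enumerate(durations):
            n = int(round(d / 0.02))
            t_parts.append(t0 + np.arange(n + 1) * 0.02)
            pen_parts.append(np.ones(n + 1, bool))
            t0 = t_parts[-1][-1]
            if k < len(durations) - 1:
                m = int(round(gap / 0.02))
                t_parts.append(t0 + np.arange(1, m) * 0.02)
                pen_parts.append(np.zeros(m - 1, bool))
                t0 = t_parts[-1][-1] + 0.02
        t = np.concatenate(t_parts)
        pen = np.concatenate(pen_parts)
        return make_trial(t, np.cumsum(np.ones_like(t)), np.zeros_like(t),
                          pen_down=pen, item="sequence")

    def test_equal_durations_give_equal_thirds(self):
        trial = self._seq_trial([1.0, 1.0, 1.0])
        ft = pl.fraction_times(pl.segment_sequence(trial, 3), trial)
        np.testing.assert_allclose(ft.fractions, [1 / 3] * 3, atol=1e-12)

    def test_two_one_one(self):
        trial = self._seq_trial([2.0, 1.0, 1.0])
        ft = pl.fraction_times(pl.segment_sequence(trial, 3), trial)
        np.testing.assert_allclose(ft.fractions, [0.5, 0.25, 0.25], atol=1e-12)

    def test_pen_up_gaps_excluded_by_default(self):
        short = self._seq_trial([1.0, 1.0, 1.0], gap=0.2)
        long = self._seq_trial([1.0, 1.0, 1.0], gap=2.0)
        f1 = pl.fraction_times(pl.segment_sequence(short, 3), short).fractions
        f2 = pl.fraction_times(pl.segment_sequence(long, 3), long).fractions
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_fractions_sum_to_one_and_invariances(self, noiseless_profile):
        trial = pl.generate_copy_trial(noiseless_profile, "word_mele",
                                       "spontaneous", seed=3)
        bounds = pl.segment_word(trial, 4, smooth_window=5)
        ft = pl.fraction_times(bounds, trial)
        assert ft.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        # uniform time rescaling and spatial scaling leave fractions unchanged
        # (detector configuration held fixed)
        rescaled = make_trial(trial.t * 3.0, trial.x * 2.0, trial.y * 2.0,
                              item="word_mele")
        ft2 = pl.fraction_times(pl.segment_word(rescaled, 4, smooth_window=5),
                                rescaled)
        np.testing.assert_allclose(ft.fractions, ft2.fractions, atol=1e-12)
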