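"""Element segmentation and the homothety statistic (fraction times).

Cursive words are split at the lowest points between letters: among the
local minima of canonical y along the pen-down trace, the ``n_letters - 1``
lowest ones that are mutually separated by at least 5% of the traced arc
length become transition points. Symbol sequences are split at pen lifts:
each stroke is one element, its duration running from the first to the last
frame the pen touched the surface.

The fraction time of an element is its duration over the summed element
durations; by default inter-symbol pen-up time counts for neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MismatchError, SegmentationError, TooShortError
from .io import TrialRecording, split_strokes


@dataclass
class SegmentBoundaries:
    """A partition of a trial into labelled elements.

    ``intervals`` holds (start, stop) sample indices into the parent trial,
    stop inclusive. For cursive words consecutive intervals share their
    boundary sample; for sequences intervals are the stroke extents.
    """

    element_labels: list[str]
    intervals: list[tuple[int, int]]
    kind: str  # "word" | "sequence"

    def __post_init__(self) -> None:
        if len(self.element_labels) != len(self.intervals):
            raise ValueError("one label per interval required")
        for a, b in self.intervals:
            if b <= a:
                raise ValueError(f"empty interval ({a}, {b})")


@dataclass
class FractionTimes:
    """Per-element time fractions; positive and summing to 1."""

    element_labels: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not np.all(self.fractions > 0):
            raise ValueError("fractions must be positive")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _pen_down_trace(trial: TrialRecording) -> np.ndarray:
    """Indices of pen-down samples in temporal order (strokes concatenated)."""
    idx = np.flatnonzero(trial.pen_down)
    if idx.size < 2:
        raise TooShortError("need >=2 pen-down samples to segment")
    return idx


def _arc_length(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    s = np.zeros(len(x))
    s[1:] = np.cumsum(np.hypot(np.diff(x), np.diff(y)))
    return s


#: Time constant of the y-smoothing used by the valley detector, seconds.
SMOOTH_SECONDS = 0.15


def segment_word(trial: TrialRecording, n_letters: int,
                 min_separation_fraction: float = 0.05,
                 smooth_window: int | None = None) -> SegmentBoundaries:
    """Split a connected cursive word into ``n_letters`` letter intervals.

    Transition points are the lowest-y local minima of the smoothed
    pen-down trace, greedily accepted lowest-first subject to a mutual
    arc-length separation of ``min_separation_fraction`` of the trace;
    candidates hugging either end of the trace are not eligible. The
    zero-phase moving-average smoother spans ~0.15 s at the trial's
    sampling rate (letter transitions are slower events than sample-level
    jitter); pass ``smooth_window`` to override. A per-trial
    ``manual_boundaries`` annotation overrides the search entirely.
    """
    if n_letters < 1:
        raise ValueError("n_letters must be >= 1")
    idx = _pen_down_trace(trial)
    if trial.manual_boundaries is not None:
        bnds = sorted(trial.manual_boundaries)
        if len(bnds) != n_letters - 1:
            raise SegmentationError(
                f"manual_boundaries has {len(bnds)} entries, expected {n_letters - 1}")
        cuts = [int(idx[0]), *bnds, int(idx[-1])]
        return SegmentBoundaries(
            element_labels=[f"letter_{i + 1}" for i in range(n_letters)],
            intervals=[(cuts[i], cuts[i + 1]) for i in range(n_letters)],
            kind="word")
    if n_letters == 1:
        return SegmentBoundaries(["letter_1"], [(int(idx[0]), int(idx[-1]))], "word")

    x, y = trial.x[idx], trial.y[idx]
    if smooth_window is None:
        dt = np.median(np.diff(trial.t[idx]))
        w = int(round(SMOOTH_SECONDS / dt)) if dt > 0 else 3
        smooth_window = max(3, w | 1)  # odd, >= 3
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        ys = np.convolve(np.pad(y, smooth_window // 2, mode="edge"),
                         kernel, mode="valid")[: len(y)]
    else:
        ys = y
    s = _arc_length(x, y)
    total = s[-1]
    if total <= 0:
        raise SegmentationError("zero-length trace")
    sep = min_separation_fraction * total

    interior = np.arange(1, len(ys) - 1)
    is_min = (ys[interior] <= ys[interior - 1]) & (ys[interior] <= ys[interior + 1]) \
        & ((ys[interior] < ys[interior - 1]) | (ys[interior] < ys[interior + 1]))
    cand = interior[is_min]
    # keep candidates away from the trace ends, where pen landing/lift dips live
    cand = cand[(s[cand] >= sep) & (s[cand] <= total - sep)]

    chosen: list[int] = []
    for c in cand[np.argsort(ys[cand], kind="stable")]:
        if all(abs(s[c] - s[k]) >= sep for k in chosen):
            chosen.append(int(c))
        if len(chosen) == n_letters - 1:
            break
    if len(chosen) < n_letters - 1:
        raise SegmentationError(
            f"found {len(chosen)} qualifying y-minima, need {n_letters - 1}; "
            "flag the trial for manual boundaries")
    chosen.sort()
    cuts = [0, *chosen, len(idx) - 1]
    return SegmentBoundaries(
        element_labels=[f"letter_{i + 1}" for i in range(n_letters)],
        intervals=[(int(idx[cuts[i]]), int(idx[cuts[i + 1]])) for i in range(n_letters)],
        kind="word")


def segment_sequence(trial: TrialRecording,
                     expected: int | list[str] | None = None) -> SegmentBoundaries:
    """One element per stroke; boundaries at pen lifts.

    ``expected`` may be a symbol count or a label list; a stroke-count
    mismatch raises :class:`MismatchError`.
    """
    strokes = split_strokes(trial)
    if expected is not None:
        labels = (list(expected) if not isinstance(expected, int) else
                  [f"symbol_{i + 1}" for i in range(expected)])
        if len(strokes) != len(labels):
            raise MismatchError(
                f"trial has {len(strokes)} strokes, expected {len(labels)} symbols")
    else:
        labels = [f"symbol_{i + 1}" for i in range(len(strokes))]
    intervals = [(st.start, st.start + len(st) - 1) for st in strokes]
    return SegmentBoundaries(element_labels=labels, intervals=intervals,
                             kind="sequence")


def fraction_times(bounds: SegmentBoundaries, trial: TrialRecording,
                   include_pen_up: bool = False) -> FractionTimes:
    """Fraction of execution time devoted to each element.

    For sequences, pen-up time between symbols is excluded by default (an
    element runs from its first to its last ink frame); with
    ``include_pen_up=True`` each gap is attributed to the preceding element.
    """
    durations = np.array([trial.t[b] - trial.t[a] for a, b in bounds.intervals])
    if include_pen_up and bounds.kind == "sequence":
        for k in range(len(bounds.intervals) - 1):
            durations[k] += trial.t[bounds.intervals[k + 1][0]] - trial.t[bounds.intervals[k][1]]
    total = durations.sum()
    if total <= 0:
        raise TooShortError("zero total element duration")
    return FractionTimes(element_labels=list(bounds.element_labels),
                         fractions=durations / total)
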