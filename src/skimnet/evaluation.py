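"""Detection scoring and the false-negative + false-positive error metric.

A detection task is scored per window: each ground-truth window must contain
at least one output spike (else a false negative), and the rest of the
timeline, tiled into windows of the same length, must contain none (each
spiking tile is a false positive). The scalar error is

    error = FN / (#positive windows) + FP / (#negative windows),

the sum of the miss rate and the false-alarm rate, in [0, 2], 0 iff perfect.
The denominators are the ground-truth window counts by default; the literal
reading with *detected* true-positive/true-negative counts in the
denominators is available but is undefined when nothing is detected.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import SpikeRaster
from .solver import _merge_windows

__all__ = [
    "EvalCounts",
    "match_detections",
    "error_metric",
    "windows_from_end_times",
]


@dataclass(frozen=True)
class EvalCounts:
    """Windowed detection counts: tp + fn and fp + tn partition the timeline."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_positive_windows(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative_windows(self) -> int:
        return self.fp + self.tn


def windows_from_end_times(
    end_times,
    K: int,
    delay: int = 10,
    width: int = 10,
    window: int = 200,
) -> list[tuple[int, int]]:
    """Detection windows for a trained detector, one per pattern end time.

    The analog of scoring one utterance per window in a continuous stream:
    each presentation contributes a window of length ``window`` (default the
    nominal pattern duration, 200 steps) centered on the middle of its
    trained target pulse ``e + delay + width/2``, so the broad soma response
    may place its rising edge anywhere in the presentation's vicinity and
    still count for it. Overlapping windows merge; windows are clipped to
    ``[0, K)``.
    """
    half = window // 2
    centers = [e + delay + width // 2 for e in end_times]
    return _merge_windows(
        (max(0, min(c - half, K)), min(c + half, K)) for c in centers
    )


def match_detections(
    output: SpikeRaster,
    truth_windows,
    K: int,
    channel: int = 0,
    window_length: int | None = None,
) -> EvalCounts:
    """Score output spikes against ground-truth windows.

    A (merged) truth window holding >= 1 output spike on ``channel`` is a
    true positive, else a false negative. The complement of the truth
    windows is tiled into consecutive windows of ``window_length`` (default:
    the median truth-window length); every full-length tile holding a spike
    is a false positive, the rest are true negatives. Gap remainders shorter
    than ``window_length`` are not scored — only same-length windows count
    as negatives.
    """
    windows = _merge_windows(
        (max(0, int(a)), min(K, int(b))) for a, b in truth_windows
    )
    if window_length is None:
        if not windows:
            raise ValueError("no truth windows and no window_length given")
        lengths = sorted(b - a for a, b in windows)
        window_length = lengths[len(lengths) // 2]
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    spike_times = sorted(t for t, c in output.events if c == channel)

    def n_spikes_in(a: int, b: int) -> int:
        import bisect
        return bisect.bisect_left(spike_times, b) - bisect.bisect_left(spike_times, a)

    tp = sum(1 for a, b in windows if n_spikes_in(a, b) > 0)
    fn = len(windows) - tp
    # Tile the complement.
    fp = tn = 0
    gaps = []
    cursor = 0
    for a, b in windows:
        if a > cursor:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < K:
        gaps.append((cursor, K))
    for ga, gb in gaps:
        t = ga
        while t + window_length <= gb:
            if n_spikes_in(t, t + window_length) > 0:
                fp += 1
            else:
                tn += 1
            t += window_length
    return EvalCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def error_metric(counts: EvalCounts, interpretation: str = "ground_truth") -> float:
    """Miss rate plus false-alarm rate.

    ``ground_truth`` (default): fn / (tp + fn) + fp / (fp + tn), i.e. the
    denominators are the ground-truth positive and negative window counts.
    ``detected``: divide by the detected tp and tn counts instead (the
    literal reading); raises when either is zero.
    """
    if interpretation == "ground_truth":
        n_pos, n_neg = counts.n_positive_windows, counts.n_negative_windows
        if n_pos == 0 or n_neg == 0:
            raise ValueError("need at least one positive and one negative window")
        return counts.fn / n_pos + counts.fp / n_neg
    if interpretation == "detected":
        if counts.tp == 0 or counts.tn == 0:
            raise ValueError(
                "detected-count denominators are zero (tp or tn == 0)"
            )
        return counts.fn / counts.tp + counts.fp / counts.tn
    raise ValueError(f"unknown interpretation {interpretation!r}")
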