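"""Cleaning and enrichment of raw CGM series.

Training-time cleaning: gap detection, first-order (linear) interpolation
across short missing intervals, and a small centred median filter to
remove spikes.  Test-time cleaning must be causal, so missing test samples
are instead estimated by linear extrapolation of the recent trend.  This
module also builds the two-phase transfer-learning corpus that combines a
target subject's full record with fixed shares of donor subjects.

Every mutating operation can append structured entries to an optional
``log`` list (dicts, one per touched slot group) which the CLI serialises
as JSON lines.
"""

from __future__ import annotations

import numpy as np

from .simulate import SLOT_MINUTES, SLOTS_PER_DAY, SubjectSeries

__all__ = [
    "detect_gaps",
    "fill_gaps_linear",
    "median_filter",
    "extrapolate_forward",
    "time_index",
    "build_transfer_corpus",
    "preprocess_training",
]


def detect_gaps(series: SubjectSeries) -> list[tuple[int, int]]:
    """Maximal runs of invalid slots as (start_slot, length) pairs.

    A slot is invalid when its mask is false or its glucose reading is
    non-positive (clinical exports encode missing readings as literal 0).
    """
    invalid = ~series.valid_mask | (series.glucose <= 0)
    if not invalid.any():
        return []
    d = np.diff(invalid.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if invalid[0]:
        starts.insert(0, 0)
    if invalid[-1]:
        ends.append(len(invalid))
    return [(s, e - s) for s, e in zip(starts, ends)]


def fill_gaps_linear(
    series: SubjectSeries,
    max_gap_slots: int = 24,
    log: list | None = None,
) -> SubjectSeries:
    """Fill short gaps by the straight line between the bounding samples.

    Training-time only: the fill uses the sample *after* the gap.  Gaps
    longer than ``max_gap_slots``, and gaps touching a series boundary,
    are left untouched (longer gaps split the record into independent
    segments at windowing time).  Idempotent; valid samples never change.
    """
    out = series.copy()
    for start, length in detect_gaps(series):
        if length > max_gap_slots:
            continue
        left, right = start - 1, start + length
        if left < 0 or right >= len(series):
            continue  # no bounding sample on one side
        g0, g1 = series.glucose[left], series.glucose[right]
        frac = np.arange(1, length + 1) / (length + 1)
        out.glucose[start : start + length] = g0 + frac * (g1 - g0)
        out.valid_mask[start : start + length] = True
        if log is not None:
            log.append(
                {
                    "op": "fill_linear",
                    "start_slot": int(start),
                    "length": int(length),
                    "left_value": float(g0),
                    "right_value": float(g1),
                }
            )
    return out


def median_filter(
    series: SubjectSeries,
    window_slots: int = 5,
    log: list | None = None,
) -> SubjectSeries:
    """Centred running median on the glucose channel.

    The window shrinks symmetrically near the edges so the output length
    equals the input length.  Only glucose changes; the filtered value at
    every slot is bounded by the min/max of its window.
    """
    if window_slots < 1 or window_slots % 2 == 0:
        raise ValueError("window_slots must be odd and >= 1")
    g = series.glucose
    n = len(g)
    out = series.copy()
    if window_slots == 1 or n == 0:
        return out
    half = window_slots // 2
    filtered = np.empty(n)
    if n >= window_slots:
        from numpy.lib.stride_tricks import sliding_window_view

        filtered[half : n - half] = np.median(
            sliding_window_view(g, window_slots), axis=1
        )
    for i in range(min(half, n)):
        k = min(i, n - 1 - i, half)
        filtered[i] = np.median(g[i - k : i + k + 1])
    for i in range(max(n - half, 0), n):
        k = min(i, n - 1 - i, half)
        filtered[i] = np.median(g[i - k : i + k + 1])
    if log is not None:
        changed = np.where(filtered != g)[0]
        for i in changed:
            log.append(
                {
                    "op": "median_filter",
                    "slot": int(i),
                    "before": float(g[i]),
                    "after": float(filtered[i]),
                }
            )
    out.glucose = filtered
    return out


def extrapolate_forward(
    history: np.ndarray,
    history_mask: np.ndarray,
    n_missing: int,
    trend_slots: int = 6,
) -> tuple[np.ndarray, bool]:
    """Causal estimates for the next ``n_missing`` slots.

    Fits a least-squares line through the last ``trend_slots`` valid
    samples of ``history`` and continues it; with fewer than 2 valid
    trailing samples it falls back to holding the last value (or 0 with
    no valid history at all) and flags the fallback.  Never looks at
    anything after the end of ``history``.
    """
    if n_missing < 1:
        return np.empty(0), False
    history = np.asarray(history, dtype=float)
    history_mask = np.asarray(history_mask, dtype=bool)
    valid_idx = np.where(history_mask)[0]
    tail = valid_idx[-trend_slots:]
    n = len(history)
    future = np.arange(n, n + n_missing, dtype=float)
    if len(tail) < 2:
        last = history[tail[-1]] if len(tail) else 0.0
        return np.full(n_missing, last), True
    slope, intercept = np.polyfit(tail.astype(float), history[tail], 1)
    return intercept + slope * future, False


def time_index(timestamp: np.datetime64) -> float:
    """Fraction of the day in [0, 1): midnight -> 0.0, noon -> 0.5.

    The timestamp must sit on the 5-minute grid (288 slots per day).
    """
    ts = np.datetime64(timestamp, "m")
    minute_of_day = int(
        (ts - ts.astype("datetime64[D]").astype("datetime64[m]"))
        / np.timedelta64(1, "m")
    )
    if minute_of_day % SLOT_MINUTES != 0:
        raise ValueError(f"timestamp {timestamp} is not on the 5-minute grid")
    return (minute_of_day // SLOT_MINUTES) / SLOTS_PER_DAY


def build_transfer_corpus(
    target: SubjectSeries, others: list[SubjectSeries]
) -> list[SubjectSeries]:
    """Combine a target subject with donor shares for phase-1 training.

    The corpus doubles the target's length: the first half is all of the
    target, the second half is split equally among the donors (with five
    donors, each contributes 10% of the combined corpus = 20% of the
    target's length).  Each donation is the final contiguous block of the
    donor's record, so the selection is deterministic.  The pieces are
    returned as separate series; windows never cross the boundaries.
    """
    if not others:
        raise ValueError("at least one donor subject is required")
    share = len(target) // len(others)
    corpus = [target]
    for donor in others:
        if len(donor) < share:
            raise ValueError(
                f"donor {donor.subject_id!r} has {len(donor)} slots but "
                f"{share} are required"
            )
        piece = donor.copy()
        piece.glucose = donor.glucose[-share:].copy()
        piece.bolus = donor.bolus[-share:].copy()
        piece.meal = donor.meal[-share:].copy()
        piece.valid_mask = donor.valid_mask[-share:].copy()
        piece.start_time = donor.timestamps[len(donor) - share]
        corpus.append(piece)
    return corpus


def preprocess_training(
    series: SubjectSeries,
    max_gap_slots: int = 24,
    median_window: int = 5,
    log: list | None = None,
) -> SubjectSeries:
    """Standard training-time cleaning: interpolate short gaps, then
    median-filter the glucose channel."""
    return median_filter(
        fill_gaps_linear(series, max_gap_slots, log=log), median_window, log=log
    )
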