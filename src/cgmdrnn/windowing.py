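"""Sliding-window extraction for sequence-to-one glucose forecasting.

Each training example is a window of 12 five-minute steps over four
channels ordered [G, I, M, T] — glucose (mg/dL), insulin bolus (units),
meal carbohydrate (g) and the time-of-day index in [0, 1) — paired with a
scalar label: the glucose *change* over the 30-minute horizon,
y = G(t + 6) - G(t).  Windows slide with stride 1 and never cross an
unfilled gap, so every input slot precedes the label slot and no window
mixes two subjects.

G, I and M are standardised with statistics fitted on training windows
only; the time channel is already in [0, 1) and passes through; labels
stay in mg/dL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .preprocess import SLOTS_PER_DAY, detect_gaps
from .simulate import SubjectSeries

N_CHANNELS = 4

__all__ = [
    "ChannelScaler",
    "WindowSet",
    "make_windows",
    "fit_scaler",
    "apply_scaler",
    "split_train_val",
    "batch_iter",
    "concat_window_sets",
]


@dataclass
class ChannelScaler:
    """Per-channel affine standardisation; the time channel passes through."""

    mean: np.ndarray  # [C]
    scale: np.ndarray  # [C]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelScaler":
        return cls(mean=np.asarray(d["mean"]), scale=np.asarray(d["scale"]))


@dataclass
class WindowSet:
    """Supervised windows: inputs [n, T, C], ΔBG labels [n] in mg/dL.

    ``last_glucose`` holds the unnormalised current reading x_T per
    window (the forecast is ΔBG + x_T); ``anchors`` records
    (subject_id, slot index of x_T) for traceability.
    """

    inputs: np.ndarray
    labels: np.ndarray
    last_glucose: np.ndarray
    anchors: list[tuple[str, int]]
    scaler: ChannelScaler | None = None
    scaled: bool = False

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            inputs=self.inputs[idx],
            labels=self.labels[idx],
            last_glucose=self.last_glucose[idx],
            anchors=[self.anchors[i] for i in np.atleast_1d(idx)],
            scaler=self.scaler,
            scaled=self.scaled,
        )

    def save(self, path: str) -> None:
        """Arrays as .npz next to a JSON sidecar for anchors/scaler."""
        np.savez(
            path + ".npz",
            inputs=self.inputs,
            labels=self.labels,
            last_glucose=self.last_glucose,
        )
        side = {
            "anchors": [[s, int(i)] for s, i in self.anchors],
            "scaler": self.scaler.to_dict() if self.scaler else None,
            "scaled": self.scaled,
        }
        with open(path + ".json", "w") as fh:
            json.dump(side, fh)

    @classmethod
    def load(cls, path: str) -> "WindowSet":
        arrs = np.load(path + ".npz")
        with open(path + ".json") as fh:
            side = json.load(fh)
        return cls(
            inputs=arrs["inputs"],
            labels=arrs["labels"],
            last_glucose=arrs["last_glucose"],
            anchors=[(s, int(i)) for s, i in side["anchors"]],
            scaler=ChannelScaler.from_dict(side["scaler"]) if side["scaler"] else None,
            scaled=side["scaled"],
        )


def _slot_of_day(series: SubjectSeries) -> np.ndarray:
    ts0 = np.datetime64(series.start_time, "m")
    midnight = ts0.astype("datetime64[D]").astype("datetime64[m]")
    first = int((ts0 - midnight) / np.timedelta64(5, "m"))
    return (first + np.arange(len(series))) % SLOTS_PER_DAY


def make_windows(
    series: SubjectSeries, seq_len: int = 12, horizon_slots: int = 6
) -> WindowSet:
    """All stride-1 windows whose slots lie in one contiguous valid run.

    A window anchored at slot t covers inputs t-seq_len+1 .. t and is
    labelled G(t+horizon) - G(t); it is kept only when every involved
    slot (including the target) is valid.  Too-short series yield an
    empty WindowSet.
    """
    if seq_len < 1 or horizon_slots < 1:
        raise ValueError("seq_len and horizon_slots must be >= 1")
    tchan = _slot_of_day(series) / SLOTS_PER_DAY
    channels = np.stack(
        [series.glucose, series.bolus, series.meal, tchan], axis=1
    ).astype(float)

    # contiguous valid runs = complement of the detected gaps
    runs: list[tuple[int, int]] = []
    pos = 0
    for start, length in detect_gaps(series) + [(len(series), 0)]:
        if start > pos:
            runs.append((pos, start - pos))
        pos = start + length

    inputs, labels, lastg, anchors = [], [], [], []
    need = seq_len + horizon_slots
    for start, length in runs:
        if length < need:
            continue
        for anchor in range(start + seq_len - 1, start + length - horizon_slots):
            w0 = anchor - seq_len + 1
            inputs.append(channels[w0 : anchor + 1])
            labels.append(series.glucose[anchor + horizon_slots] - series.glucose[anchor])
            lastg.append(series.glucose[anchor])
            anchors.append((series.subject_id, anchor))
    if not inputs:
        t = seq_len
        return WindowSet(
            inputs=np.empty((0, t, N_CHANNELS)),
            labels=np.empty(0),
            last_glucose=np.empty(0),
            anchors=[],
        )
    return WindowSet(
        inputs=np.stack(inputs),
        labels=np.asarray(labels),
        last_glucose=np.asarray(lastg),
        anchors=anchors,
    )


def fit_scaler(train: WindowSet) -> ChannelScaler:
    """Mean/SD per channel over all training windows and timesteps.

    The time channel (index 3) passes through unchanged; a zero-variance
    channel gets scale 1 so it is only mean-shifted.
    """
    flat = train.inputs.reshape(-1, train.inputs.shape[-1])
    mean = flat.mean(axis=0)
    scale = flat.std(axis=0)
    scale[scale == 0.0] = 1.0
    mean[3] = 0.0
    scale[3] = 1.0
    return ChannelScaler(mean=mean, scale=scale)


def apply_scaler(ws: WindowSet, scaler: ChannelScaler) -> WindowSet:
    """Return a standardised copy; labels and x_T stay in mg/dL."""
    return WindowSet(
        inputs=scaler.transform(ws.inputs),
        labels=ws.labels.copy(),
        last_glucose=ws.last_glucose.copy(),
        anchors=list(ws.anchors),
        scaler=scaler,
        scaled=True,
    )


def split_train_val(
    ws: WindowSet, val_frac: float = 0.1
) -> tuple[WindowSet, WindowSet]:
    """Chronological split: the last ceil(val_frac * n) windows validate."""
    if not 0.0 < val_frac < 1.0:
        raise ValueError("val_frac must lie in (0, 1)")
    n = len(ws)
    n_val = int(np.ceil(val_frac * n))
    return ws.subset(np.arange(0, n - n_val)), ws.subset(np.arange(n - n_val, n))


def batch_iter(
    ws: WindowSet,
    batch_size: int = 512,
    seed: int = 0,
    epoch: int = 0,
    shuffle: bool = True,
):
    """Yield per-epoch mini-batches as index arrays.

    A seeded shuffle, reproducible per (seed, epoch), partitioned into
    batches; the final short batch is kept.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    n = len(ws)
    if n == 0:
        return
    order = np.arange(n)
    if shuffle:
        np.random.default_rng([seed, epoch]).shuffle(order)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def concat_window_sets(sets: list[WindowSet]) -> WindowSet:
    """Concatenate window sets from multiple series (corpus building)."""
    sets = [s for s in sets if len(s) > 0]
    if not sets:
        raise ValueError("no non-empty window sets to concatenate")
    return WindowSet(
        inputs=np.concatenate([s.inputs for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        last_glucose=np.concatenate([s.last_glucose for s in sets]),
        anchors=[a for s in sets for a in s.anchors],
        scaler=sets[0].scaler,
        scaled=sets[0].scaled,
    )
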