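"""Reading and writing subject series, scenarios and reports.

The on-disk series format is a CSV with columns ``timestamp`` (ISO 8601,
5-min grid), ``glucose_mgdl``, ``bolus_units``, ``meal_carbs_g`` and
``valid`` (0/1).  Missing glucose is written as an empty field with
valid=0; on input, the clinical convention of literal 0 readings is also
mapped to valid=0.  Scenarios round-trip through YAML.  An optional
reader maps OhioT1DM-style XML event lists onto the same grid (that
dataset itself is distributed under a data-use agreement and is not
required anywhere in this package).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml

from .simulate import SLOT_MINUTES, Physiology, SimScenario, SubjectSeries

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "read_ohio_xml",
]


def write_series_csv(series: SubjectSeries, path: str) -> None:
    glucose = [
        "" if not v else f"{g:.6g}"
        for g, v in zip(series.glucose, series.valid_mask)
    ]
    df = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(series.timestamps).strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "glucose_mgdl": glucose,
            "bolus_units": series.bolus,
            "meal_carbs_g": series.meal,
            "valid": series.valid_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_series_csv(path: str, subject_id: str | None = None) -> SubjectSeries:
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"])
    if len(ts) > 1:
        deltas = np.diff(ts.values).astype("timedelta64[m]")
        if not np.all(deltas == np.timedelta64(SLOT_MINUTES, "m")):
            raise ValueError(f"{path}: timestamps are not on a strict 5-min grid")
    glucose = pd.to_numeric(df["glucose_mgdl"], errors="coerce").to_numpy(float)
    valid = df["valid"].to_numpy(bool)
    valid &= np.isfinite(glucose) & (glucose > 0)  # literal 0 => invalid
    glucose = np.where(np.isfinite(glucose), glucose, 0.0)
    return SubjectSeries(
        subject_id=subject_id or str(path),
        start_time=np.datetime64(ts.iloc[0], "m"),
        glucose=glucose,
        bolus=df["bolus_units"].to_numpy(float),
        meal=df["meal_carbs_g"].to_numpy(float),
        valid_mask=valid,
    )


def scenario_to_yaml(scenario: SimScenario, path: str) -> None:
    d = dataclasses.asdict(scenario)
    d["boluses_per_day_range"] = list(scenario.boluses_per_day_range)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def scenario_from_yaml(path: str) -> SimScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    phys = Physiology(**d.pop("physiology", {}))
    rng = d.pop("boluses_per_day_range", (1, 5))
    return SimScenario(
        physiology=phys, boluses_per_day_range=tuple(rng), **d
    )


def _parse_ts(value: str) -> np.datetime64:
    # OhioT1DM uses "dd-mm-yyyy hh:mm:ss"; ISO 8601 is accepted too
    ts = pd.to_datetime(value, dayfirst=len(value) > 2 and value[2] == "-")
    return np.datetime64(ts, "m")


def read_ohio_xml(path: str, subject_id: str | None = None) -> SubjectSeries:
    """Map an OhioT1DM-style XML export onto the 5-minute grid.

    Expects ``<glucose_level><event ts=... value=.../></glucose_level>``
    plus optional ``<bolus>`` (attribute ``dose``) and ``<meal>``
    (attribute ``carbs``) event lists.  Events snap to the nearest slot;
    slots without a glucose reading are marked invalid.
    """
    from lxml import etree

    tree = etree.parse(path)
    root = tree.getroot()
    sid = subject_id or root.get("id", "ohio")

    def events(tag: str, value_attr: str):
        out = []
        for ev in root.iter(tag):
            for e in ev.iter("event"):
                ts = e.get("ts") or e.get("ts_begin")
                val = e.get(value_attr)
                if ts is not None and val is not None:
                    out.append((_parse_ts(ts), float(val)))
        return out

    glucose_ev = events("glucose_level", "value")
    if not glucose_ev:
        raise ValueError(f"{path}: no glucose events found")
    t0 = min(t for t, _ in glucose_ev)
    t1 = max(t for t, _ in glucose_ev)
    t0 -= np.timedelta64(int(t0.astype("int64")) % SLOT_MINUTES, "m")
    n = int((t1 - t0) / np.timedelta64(SLOT_MINUTES, "m")) + 1

    glucose = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    bolus = np.zeros(n)
    meal = np.zeros(n)

    def slot(ts: np.datetime64) -> int:
        return int(round((ts - t0) / np.timedelta64(SLOT_MINUTES, "m")))

    for ts, v in glucose_ev:
        i = slot(ts)
        if 0 <= i < n and v > 0:
            glucose[i] = v
            valid[i] = True
    for ts, v in events("bolus", "dose"):
        i = slot(ts)
        if 0 <= i < n:
            bolus[i] += v
    for ts, v in events("meal", "carbs"):
        i = slot(ts)
        if 0 <= i < n:
            meal[i] += v
    return SubjectSeries(
        subject_id=sid,
        start_time=t0,
        glucose=glucose,
        bolus=bolus,
        meal=meal,
        valid_mask=valid,
    )
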