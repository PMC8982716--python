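"""Synthetic CGM cohort generation.

Virtual type-1 diabetes subjects are produced by a Bergman-style minimal
model of glucose--insulin dynamics extended with a two-compartment gut
absorption chain for meals and a two-compartment subcutaneous absorption
chain for insulin boluses:

    dG/dt  = -p1 (G - Gb) - X G + Ra(t) / V
    dX/dt  = -p2 X + p3 (Ip - Ib)
    dQ1/dt = -k_gut Q1              dQ2/dt = k_gut (Q1 - Q2)
    dS1/dt = -k_sc S1               dS2/dt = k_sc (S1 - S2)
    dIp/dt = -k_cl (Ip - Ib) + k_sc S2 * 1e6 / Vi

with glucose rate of appearance Ra = f_bio * k_gut * Q2 and remote insulin
action X driven by plasma insulin Ip above basal Ib.  Meals are impulses of
carbohydrate mass into Q1; boluses are impulses of insulin units into S1.
The ODE system is integrated with fixed-step RK4 at a 1-minute internal
step and subsampled to the 5-minute CGM grid; autocorrelated AR(1) sensor
noise is added on top of the ODE output.

Daily event statistics follow the standard virtual-cohort protocol: three
meals per day with 10% coefficient of variation in size and 20-minute
standard deviation in timing, and between 1 and 5 insulin boluses per day
that need not coincide with meals.

Clinical-style sensor defects (missing intervals, additive spikes, frozen
readings) are injected by separate operations so that every downstream
stage can be exercised on data with the failure modes real CGM traces show.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

SLOT_MINUTES = 5
SLOTS_PER_DAY = 288
MINUTES_PER_DAY = 1440

__all__ = [
    "Physiology",
    "SimScenario",
    "SubjectSeries",
    "simulate_subject",
    "inject_missingness",
    "inject_outliers",
    "inject_frozen_sensor",
    "SLOT_MINUTES",
    "SLOTS_PER_DAY",
]


@dataclass(frozen=True)
class Physiology:
    """Minimal-model parameters for one virtual subject.

    Rates are per minute; volumes in dL (glucose) and mL (insulin).
    Defaults give a ~70 kg adult with T1DM-like insulin sensitivity:
    a 50 g meal raises glucose by roughly 60-100 mg/dL and a matched
    bolus brings it back over 3-4 h.
    """

    p1: float = 0.006        # glucose effectiveness, 1/min
    p2: float = 0.025        # remote insulin decay, 1/min
    p3: float = 1.3e-5       # insulin action gain, 1/min^2 per uU/mL
    Gb: float = 130.0        # basal glucose, mg/dL
    Ib: float = 10.0         # basal plasma insulin, uU/mL
    V: float = 140.0         # glucose distribution volume, dL
    Vi: float = 8400.0       # insulin distribution volume, mL
    k_gut: float = 0.028     # gut chain rate, 1/min (Ra peak ~36 min)
    k_sc: float = 0.02       # subcutaneous chain rate, 1/min
    k_cl: float = 0.2        # plasma insulin clearance, 1/min
    f_bio: float = 0.8       # carbohydrate bioavailability
    carb_ratio: float = 10.0  # grams of carbohydrate covered per unit

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"physiology parameter {f.name!r} must be positive, got {v}"
                )


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic subject."""

    n_days: int = 30
    meals_per_day: int = 3
    meal_size_mean: float = 55.0     # g carbohydrate
    meal_size_cv: float = 0.10
    meal_time_std: float = 20.0      # minutes
    boluses_per_day_range: tuple[int, int] = (1, 5)
    physiology: Physiology = field(default_factory=Physiology)
    sensor_noise_sd: float = 2.5     # mg/dL, marginal SD of AR(1) noise
    sensor_noise_rho: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.meal_size_cv < 0:
            raise ValueError("meal_size_cv must be >= 0")
        lo, hi = self.boluses_per_day_range
        if not (0 <= lo <= hi <= 24):
            raise ValueError("boluses_per_day_range must lie within [0, 24]")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")
        self.physiology.validate()


@dataclass
class SubjectSeries:
    """One subject's multi-channel record on the 5-minute CGM grid.

    ``glucose`` is mg/dL, ``bolus`` insulin units at the administration
    slot (0 elsewhere), ``meal`` grams of carbohydrate at the intake slot,
    and ``valid_mask`` flags slots holding a usable glucose reading.
    """

    subject_id: str
    start_time: np.datetime64
    glucose: np.ndarray
    bolus: np.ndarray
    meal: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.glucose)
        if not (len(self.bolus) == len(self.meal) == len(self.valid_mask) == n):
            raise ValueError("channel arrays must have equal length")

    def __len__(self) -> int:
        return len(self.glucose)

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) * np.timedelta64(
            SLOT_MINUTES, "m"
        )

    def copy(self) -> "SubjectSeries":
        return SubjectSeries(
            subject_id=self.subject_id,
            start_time=self.start_time,
            glucose=self.glucose.copy(),
            bolus=self.bolus.copy(),
            meal=self.meal.copy(),
            valid_mask=self.valid_mask.copy(),
        )


def _daily_events(scenario: SimScenario, rng: np.random.Generator):
    """Draw meal and bolus (time_min, amount) events for every day."""
    phys = scenario.physiology
    meals: list[tuple[float, float]] = []
    boluses: list[tuple[float, float]] = []
    if scenario.meals_per_day == 3:
        anchors = np.array([7.5, 12.5, 18.5]) * 60.0
    else:
        anchors = np.linspace(7.0, 19.0, max(scenario.meals_per_day, 1)) * 60.0
    lo, hi = scenario.boluses_per_day_range
    for day in range(scenario.n_days):
        day0 = day * MINUTES_PER_DAY
        times = anchors + rng.normal(0.0, scenario.meal_time_std, size=len(anchors))
        times = np.clip(times, 0.0, MINUTES_PER_DAY - 1.0)
        sizes = scenario.meal_size_mean * (
            1.0 + scenario.meal_size_cv * rng.standard_normal(len(anchors))
        )
        sizes = np.maximum(sizes, 5.0)
        for t, s in zip(times, sizes):
            meals.append((day0 + t, s))
        n_bolus = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        if n_bolus > 0:
            total_units = sizes.sum() / phys.carb_ratio
            # boluses land near (but not exactly at) meal times
            picks = rng.choice(len(anchors), size=n_bolus, replace=True)
            b_times = times[picks] + rng.normal(0.0, 15.0, size=n_bolus)
            b_times = np.clip(b_times, 0.0, MINUTES_PER_DAY - 1.0)
            shares = rng.dirichlet(np.full(n_bolus, 5.0))
            for t, w in zip(b_times, shares):
                boluses.append((day0 + t, total_units * w))
    return meals, boluses


def _integrate(
    phys: Physiology,
    n_minutes: int,
    meal_mg_per_min: np.ndarray,
    bolus_units_per_min: np.ndarray,
) -> np.ndarray:
    """RK4 at 1-min steps; returns glucose at every minute boundary."""

    p1, p2, p3 = phys.p1, phys.p2, phys.p3
    Gb, Ib, V, Vi = phys.Gb, phys.Ib, phys.V, phys.Vi
    kg, ks, kc = phys.k_gut, phys.k_sc, phys.k_cl

    def deriv(s):
        G, X, Q1, Q2, S1, S2, Ip = s
        Ra = phys.f_bio * kg * Q2
        return (
            -p1 * (G - Gb) - X * G + Ra / V,
            -p2 * X + p3 * (Ip - Ib),
            -kg * Q1,
            kg * (Q1 - Q2),
            -ks * S1,
            ks * (S1 - S2),
            -kc * (Ip - Ib) + ks * S2 * 1e6 / Vi,
        )

    state = [Gb, 0.0, 0.0, 0.0, 0.0, 0.0, Ib]
    out = np.empty(n_minutes + 1)
    out[0] = state[0]
    h = 1.0
    for m in range(n_minutes):
        # impulse inputs at the start of the minute
        state[2] += meal_mg_per_min[m]
        state[4] += bolus_units_per_min[m]
        k1 = deriv(state)
        s2 = [s + 0.5 * h * k for s, k in zip(state, k1)]
        k2 = deriv(s2)
        s3 = [s + 0.5 * h * k for s, k in zip(state, k2)]
        k3 = deriv(s3)
        s4 = [s + h * k for s, k in zip(state, k3)]
        k4 = deriv(s4)
        state = [
            s + (h / 6.0) * (a + 2 * b + 2 * c + d)
            for s, a, b, c, d in zip(state, k1, k2, k3, k4)
        ]
        state[0] = max(state[0], 20.0)  # physiological floor
        out[m + 1] = state[0]
    return out


def simulate_subject(
    scenario: SimScenario, subject_id: str = "sim-000"
) -> SubjectSeries:
    """Generate one defect-free virtual subject.

    The output has ``n_days * 288`` slots, every slot valid, and is
    bitwise reproducible for a fixed (scenario, seed) pair.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n_slots = scenario.n_days * SLOTS_PER_DAY
    n_minutes = n_slots * SLOT_MINUTES

    meals, boluses = _daily_events(scenario, rng)

    meal_in = np.zeros(n_minutes)
    meal_ch = np.zeros(n_slots)
    for t_min, grams in meals:
        m = min(int(round(t_min)), n_minutes - 1)
        meal_in[m] += grams * 1000.0  # g -> mg into the gut chain
        meal_ch[min(m // SLOT_MINUTES, n_slots - 1)] += grams
    bolus_in = np.zeros(n_minutes)
    bolus_ch = np.zeros(n_slots)
    for t_min, units in boluses:
        m = min(int(round(t_min)), n_minutes - 1)
        bolus_in[m] += units
        bolus_ch[min(m // SLOT_MINUTES, n_slots - 1)] += units

    g_min = _integrate(scenario.physiology, n_minutes, meal_in, bolus_in)
    glucose = g_min[: n_minutes : SLOT_MINUTES].copy()

    if scenario.sensor_noise_sd > 0:
        rho = scenario.sensor_noise_rho
        w = rng.standard_normal(n_slots)
        noise = np.empty(n_slots)
        noise[0] = w[0]
        innov = np.sqrt(1.0 - rho * rho)
        for i in range(1, n_slots):
            noise[i] = rho * noise[i - 1] + innov * w[i]
        glucose = glucose + scenario.sensor_noise_sd * noise
    glucose = np.maximum(glucose, 20.0)

    return SubjectSeries(
        subject_id=subject_id,
        start_time=np.datetime64("2024-01-01T00:00"),
        glucose=glucose,
        bolus=bolus_ch,
        meal=meal_ch,
        valid_mask=np.ones(n_slots, dtype=bool),
    )


def inject_missingness(
    series: SubjectSeries,
    gap_starts: list[int],
    gap_lengths: list[int],
    seed: int = 0,
) -> SubjectSeries:
    """Invalidate the requested slot runs; other channels are untouched.

    ``gap_starts`` are slot indices; gaps must be disjoint and lie inside
    the series.  The seed is accepted for interface symmetry with the
    random defect injectors (this operation is deterministic).
    """
    if len(gap_starts) != len(gap_lengths):
        raise ValueError("gap_starts and gap_lengths must have equal length")
    out = series.copy()
    covered = np.zeros(len(series), dtype=bool)
    for start, length in zip(gap_starts, gap_lengths):
        if length < 1:
            raise ValueError("gap lengths must be >= 1")
        if start < 0 or start + length > len(series):
            raise ValueError(f"gap ({start}, {length}) out of range")
        if covered[start : start + length].any():
            raise ValueError(f"gap ({start}, {length}) overlaps another gap")
        covered[start : start + length] = True
    out.valid_mask[covered] = False
    return out


def inject_outliers(
    series: SubjectSeries,
    rate: float,
    magnitude_sd: float,
    seed: int = 0,
) -> tuple[SubjectSeries, np.ndarray]:
    """Add seeded Gaussian spikes to ~``rate`` of the valid slots.

    Returns the perturbed series and the per-slot spike amounts (zero
    where untouched) so callers can audit exactly what changed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if magnitude_sd < 0:
        raise ValueError("magnitude_sd must be >= 0")
    out = series.copy()
    spikes = np.zeros(len(series))
    if rate == 0.0:
        return out, spikes
    rng = np.random.default_rng(seed)
    hit = rng.random(len(series)) < rate
    hit &= series.valid_mask
    amounts = rng.standard_normal(int(hit.sum())) * magnitude_sd
    new_vals = np.maximum(out.glucose[hit] + amounts, 1.0)
    spikes[hit] = new_vals - out.glucose[hit]
    out.glucose[hit] = new_vals
    return out, spikes


def inject_frozen_sensor(
    series: SubjectSeries, start_slot: int, duration_slots: int = 24
) -> SubjectSeries:
    """Freeze the glucose reading for a period (default 2 h = 24 slots).

    Emulates the stuck-sensor recording error seen in clinical traces:
    the value at ``start_slot`` repeats verbatim; the mask stays valid
    because the defect is undetectable from the mask alone.
    """
    if start_slot < 0 or start_slot + duration_slots > len(series):
        raise ValueError("frozen interval out of range")
    out = series.copy()
    out.glucose[start_slot : start_slot + duration_slots] = out.glucose[start_slot]
    return out
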