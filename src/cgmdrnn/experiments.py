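"""End-to-end experiments on synthetic cohorts.

Two study designs are provided, both fully seeded:

* ``run_cohort_benchmark`` — simulate a cohort, train the dilated RNN
  and the ARX baseline per subject on identical windows, and evaluate
  RMSE / MARD / time lag on a held-out chronological test block.  The
  qualitative question is whether the recurrent model beats the linear
  baseline in accuracy and reaction delay.
* ``run_transfer_experiment`` — on a cohort sharing physiology, compare
  two-phase transfer learning against training from scratch on the
  target subject at an equal total epoch budget.

Problem sizes default to a desk-scale protocol (a handful of subjects,
weeks rather than a year of data, a bounded epoch budget at which the
validation loss has plateaued on this generator's output); all sizes are
keyword-adjustable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import model as drnn
from .baselines import arx_fit, arx_predict, nnpg_predict, nnpg_train, svr_predict, svr_train
from .evaluation import MetricsReport, mard, rmse, time_lag
from .simulate import Physiology, SimScenario, SubjectSeries, simulate_subject
from .training import TrainConfig, train, transfer_train, windows_from_series
from .windowing import apply_scaler, fit_scaler, make_windows, split_train_val

SLOTS_PER_DAY = 288

__all__ = [
    "make_cohort",
    "split_series",
    "run_cohort_benchmark",
    "run_transfer_experiment",
]


def _vary_physiology(base: Physiology, rng: np.random.Generator,
                     cv: float = 0.10) -> Physiology:
    """Per-subject parameter variation: lognormal jitter on the rates."""
    jitter = {
        name: getattr(base, name) * float(np.exp(rng.normal(0.0, cv)))
        for name in ("p1", "p2", "p3", "k_gut", "k_sc")
    }
    return dataclasses.replace(base, **jitter)


def make_cohort(
    n_subjects: int,
    n_days: int,
    seed: int,
    base_scenario: SimScenario | None = None,
    vary_physiology: bool = True,
) -> list[SubjectSeries]:
    """Simulate a cohort of virtual subjects.

    Each subject gets an independent event stream; with
    ``vary_physiology`` the minimal-model rates also vary subject to
    subject (10% lognormal), guaranteeing inter-subject uniqueness.
    """
    base = base_scenario or SimScenario(n_days=n_days)
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        phys = (
            _vary_physiology(base.physiology, rng)
            if vary_physiology
            else base.physiology
        )
        scen = dataclasses.replace(
            base,
            n_days=n_days,
            physiology=phys,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(simulate_subject(scen, subject_id=f"sim-{i:03d}"))
    return cohort


def split_series(series: SubjectSeries, train_days: int) -> tuple[SubjectSeries, SubjectSeries]:
    """Chronological train/test split at a whole-day boundary."""
    cut = train_days * SLOTS_PER_DAY
    if not 0 < cut < len(series):
        raise ValueError("train_days must leave both splits non-empty")
    head, tail = series.copy(), series.copy()
    head.glucose, head.bolus = series.glucose[:cut].copy(), series.bolus[:cut].copy()
    head.meal, head.valid_mask = series.meal[:cut].copy(), series.valid_mask[:cut].copy()
    tail.glucose, tail.bolus = series.glucose[cut:].copy(), series.bolus[cut:].copy()
    tail.meal, tail.valid_mask = series.meal[cut:].copy(), series.valid_mask[cut:].copy()
    tail.start_time = series.timestamps[cut]
    return head, tail


def _as32(ws):
    """Float32 working copies for the neural-network training path."""
    out = ws.subset(np.arange(len(ws)))
    out.inputs = ws.inputs.astype(np.float32)
    out.labels = ws.labels.astype(np.float32)
    return out


def _evaluate(pred: np.ndarray, actual: np.ndarray) -> dict[str, float]:
    return {
        "rmse": rmse(pred, actual),
        "mard": mard(pred, actual),
        "tau_lag": time_lag(pred, actual),
    }


def run_cohort_benchmark(
    n_subjects: int = 5,
    train_days: int = 30,
    test_days: int = 5,
    seeds: tuple[int, ...] = (0, 1, 2),
    methods: tuple[str, ...] = ("drnn", "arx"),
    drnn_config: TrainConfig | None = None,
    verbose: bool = False,
) -> dict:
    """Cohort comparison of forecasters, median-of-seeds.

    For every seed a fresh cohort is simulated; per subject each method
    is fitted on the first ``train_days`` (with a chronological 90/10
    train/validation split for the neural models) and evaluated on the
    last ``test_days``.  Returns per-seed subject-mean metrics, their
    across-seed medians, and the last seed's full report.
    """
    per_seed: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    report = None
    for seed in seeds:
        cohort = make_cohort(n_subjects, train_days + test_days, seed)
        per_subject: dict[str, dict[str, list[float]]] = {
            m: {"rmse": [], "mard": [], "tau_lag": []} for m in methods
        }
        for series in cohort:
            head, tail = split_series(series, train_days)
            train_all = make_windows(head)
            test_raw = make_windows(tail)
            tr_raw, va_raw = split_train_val(train_all, 0.1)
            scaler = fit_scaler(tr_raw)
            tr = apply_scaler(tr_raw, scaler)
            va = apply_scaler(va_raw, scaler)
            test = apply_scaler(test_raw, scaler)
            actual = test.labels + test.last_glucose

            for method in methods:
                if method == "drnn":
                    cfg = drnn_config or TrainConfig(
                        max_epochs=150, patience=25, seed=seed
                    )
                    net = drnn.DRNNModel.init(seed=cfg.seed, dtype=np.float32)
                    net, hist = train(net, _as32(tr), _as32(va), cfg)
                    pred = drnn.predict_batch(
                        net, test.inputs.astype(np.float32), test.last_glucose
                    )
                elif method == "arx":
                    arx = arx_fit(tr_raw)
                    pred = arx_predict(arx, test_raw)
                elif method == "svr":
                    svm = svr_train(tr)
                    pred = svr_predict(svm, test)
                elif method == "nnpg":
                    cfg = drnn_config or TrainConfig(
                        max_epochs=30, patience=5, seed=seed, batch_size=32
                    )
                    mlp = nnpg_train(tr, va, dataclasses.replace(cfg, batch_size=32))
                    pred = nnpg_predict(mlp, test)
                else:
                    raise ValueError(f"unknown method {method!r}")
                m = _evaluate(pred, actual)
                for k, v in m.items():
                    per_subject[method][k].append(v)
                if verbose:
                    print(
                        f"seed {seed} {series.subject_id} {method}: "
                        f"RMSE {m['rmse']:.2f} mg/dL, MARD {m['mard']:.2f}%, "
                        f"lag {m['tau_lag']:.1f} min"
                    )
        report = MetricsReport(per_subject=per_subject)
        for method in methods:
            per_seed[method].append(
                {
                    k: float(np.mean(per_subject[method][k]))
                    for k in ("rmse", "mard", "tau_lag")
                }
            )
    medians = {
        method: {
            k: float(np.median([s[k] for s in per_seed[method]]))
            for k in ("rmse", "mard", "tau_lag")
        }
        for method in methods
    }
    return {"per_seed": per_seed, "median": medians, "last_report": report}


def run_transfer_experiment(
    target_train_days: int = 8,
    donor_days: int = 8,
    n_donors: int = 5,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    phase1_epochs: int = 15,
    phase2_epochs: int = 10,
    verbose: bool = False,
) -> dict:
    """Transfer learning vs from-scratch at an equal total epoch budget.

    Donors share the target's physiology (only the event realisations
    differ), the regime where borrowing data can help a subject with a
    short record.  Validation RMSE on the target's own chronological
    split is compared; medians over seeds are reported.
    """
    transfer_rmse, scratch_rmse = [], []
    for seed in seeds:
        base = SimScenario(n_days=target_train_days)
        cohort = make_cohort(
            1 + n_donors,
            donor_days,
            seed,
            base_scenario=base,
            vary_physiology=False,
        )
        target = make_cohort(1, target_train_days, seed + 7919,
                             base_scenario=base, vary_physiology=False)[0]
        donors = cohort[1:]

        cfg = TrainConfig(max_epochs=phase1_epochs, patience=phase1_epochs,
                          phase2_epochs=phase2_epochs, seed=seed)
        model_t, h1, h2 = transfer_train(target, donors, cfg, dtype=np.float32)
        t_rmse = h2.best_val_rmse if h2.val_rmse else h1.best_val_rmse

        cfg_s = dataclasses.replace(
            cfg, max_epochs=phase1_epochs + phase2_epochs,
            patience=phase1_epochs + phase2_epochs,
        )
        tr, va = windows_from_series([target])
        model_s = drnn.DRNNModel.init(seed=seed, dtype=np.float32)
        model_s, hs = train(model_s, _as32(tr), _as32(va), cfg_s)
        transfer_rmse.append(t_rmse)
        scratch_rmse.append(hs.best_val_rmse)
        if verbose:
            print(
                f"seed {seed}: transfer {t_rmse:.3f} vs scratch "
                f"{hs.best_val_rmse:.3f} mg/dL"
            )
    return {
        "transfer_rmse": transfer_rmse,
        "scratch_rmse": scratch_rmse,
        "median_transfer": float(np.median(transfer_rmse)),
        "median_scratch": float(np.median(scratch_rmse)),
    }
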